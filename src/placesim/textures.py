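"""Wall texture registry.

Textures give the wall segments the visual structure the lowest network layer
learns from.  A registry maps texture identifiers to small RGB rasters and
decides whether every wall gets the same texture or the available set is
cycled through segment by segment.  Procedural fallback patterns (stripes,
checker, noise at distinct mean luminances) are always available so the
package runs with zero bundled image assets; image files in a user directory
override them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ParameterError

_TEX_SIZE = 64


def _procedural_textures() -> dict[str, np.ndarray]:
    """Deterministic built-in patterns at distinct mean luminances."""
    s = _TEX_SIZE
    yy, xx = np.mgrid[0:s, 0:s]
    tex: dict[str, np.ndarray] = {}

    stripes_v = np.where((xx // 8) % 2 == 0, 230, 60).astype(np.uint8)
    tex["stripes_v"] = np.stack([stripes_v, stripes_v // 2, stripes_v], axis=-1)

    stripes_h = np.where((yy // 8) % 2 == 0, 200, 30).astype(np.uint8)
    tex["stripes_h"] = np.stack(
        [stripes_h // 2, stripes_h, np.full_like(stripes_h, 90)], axis=-1
    )

    checker = np.where(((xx // 16) + (yy // 16)) % 2 == 0, 245, 90).astype(np.uint8)
    tex["checker"] = np.stack([checker, checker, checker // 3], axis=-1)

    rng = np.random.default_rng(1234)  # fixed pattern, part of the design
    noise = rng.integers(20, 160, size=(s, s), dtype=np.int64).astype(np.uint8)
    tex["noise"] = np.stack([noise, np.full_like(noise, 120), 255 - noise], axis=-1)

    diag = np.where(((xx + yy) // 10) % 2 == 0, 180, 70).astype(np.uint8)
    tex["diagonal"] = np.stack([diag, 255 - diag, diag], axis=-1)
    return tex


@dataclass
class TextureRegistry:
    """Maps texture identifiers to RGB uint8 images.

    With ``cycle`` enabled, successive wall segments draw successive textures
    from the registry's ordering; otherwise every segment uses ``default_id``.
    """

    textures: dict[str, np.ndarray] = field(default_factory=_procedural_textures)
    cycle: bool = True
    default_id: str = "stripes_v"

    def __post_init__(self):
        if not self.textures:
            raise ParameterError("registry must contain at least one texture")
        for name, img in self.textures.items():
            img = np.asarray(img)
            if img.ndim == 2:
                img = np.stack([img] * 3, axis=-1)
            self.textures[name] = img.astype(np.uint8)
        if self.default_id not in self.textures:
            self.default_id = next(iter(self.textures))

    def get(self, texture_id: str) -> np.ndarray:
        """Resolve an identifier, falling back to the default texture."""
        return self.textures.get(texture_id, self.textures[self.default_id])

    def __contains__(self, texture_id: str) -> bool:
        return texture_id in self.textures

    def id_for_index(self, index: int) -> str:
        """Texture id assigned to the ``index``-th wall segment."""
        if not self.cycle:
            return self.default_id
        names = list(self.textures)
        return names[index % len(names)]

    @classmethod
    def from_directory(cls, path: str | Path, cycle: bool = True) -> "TextureRegistry":
        """Registry from PNG/JPEG files in a directory (procedural patterns
        remain available as fallbacks under their built-in names)."""
        import imageio.v3 as iio

        path = Path(path)
        tex = _procedural_textures()
        user = {}
        for f in sorted(path.iterdir()):
            if f.suffix.lower() in (".png", ".jpg", ".jpeg"):
                img = np.asarray(iio.imread(f))
                if img.ndim == 3 and img.shape[2] > 3:
                    img = img[:, :, :3]
                user[f.stem] = img
        if not user:
            raise ParameterError(f"no image files found in {path}")
        # user textures first so cycling prefers them; procedural as fallback
        reg = cls(textures={**user, **tex}, cycle=cycle)
        reg.default_id = next(iter(user))
        return reg
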