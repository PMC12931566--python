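"""Seeded generator of skin-lesion-like RGB scenes.

Because clinical photographs cannot be redistributed, the package ships a
generator that emulates the two chromatic regimes the metrics must
distinguish:

* **nevus-like**: a single narrow Gaussian component per channel, strongly
  inter-channel correlated — chromatically uniform pigment on narrow skin;
* **melanoma-like**: broad three-component Gaussian mixtures with
  channel-specific component means and weak coupling — multimodal,
  decorrelated channel histograms (the signature of polychromia).

Each scene is an elliptical lesion on a skin background, plus a lesional
mask (the ellipse) and a perilesional mask (an elliptical ring of skin
immediately around it).  Inter-channel coupling uses one shared latent
standard-normal draw per pixel mixed with independent per-channel draws
(correlation ``rho``); the mixture component is chosen from one shared
uniform per pixel, so ``rho = 1`` with identical per-channel specs yields
bit-identical planes.  Values are rounded then clipped to [0, 255]; clipped
mass piles up at 0/255, which is acceptable for these presets (component
means sit well inside the range).

Scenes are deterministic functions of their config, including the seed.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Union

import imageio.v3 as iio
import numpy as np
import yaml

from .exceptions import ConfigError
from .roi_image import ROIMask, RGBImage

_CHANNELS = ("r", "g", "b")


@dataclass(frozen=True)
class MixtureSpec:
    """Gaussian mixture over intensities: list of (weight, mean, sd)."""

    components: tuple[tuple[float, float, float], ...]

    def __post_init__(self) -> None:
        comps = tuple(tuple(float(x) for x in c) for c in self.components)
        if not comps:
            raise ConfigError("mixture needs at least one component")
        weights = [w for w, _, _ in comps]
        if any(w < 0 for w in weights) or abs(sum(weights) - 1.0) > 1e-9:
            raise ConfigError(f"weights must be >=0 and sum to 1, got {weights}")
        if any(sd < 0 for _, _, sd in comps):
            raise ConfigError("component sds must be >= 0")
        object.__setattr__(self, "components", comps)

    @property
    def weights(self) -> np.ndarray:
        return np.array([w for w, _, _ in self.components])

    @property
    def means(self) -> np.ndarray:
        return np.array([m for _, m, _ in self.components])

    @property
    def sds(self) -> np.ndarray:
        return np.array([s for _, _, s in self.components])

    @property
    def mean(self) -> float:
        """Expected value of the mixture (before rounding/clipping)."""
        return float(self.weights @ self.means)


@dataclass(frozen=True)
class SceneConfig:
    """Geometry, per-region channel mixtures, coupling, and seed."""

    width: int
    height: int
    skin: dict  # channel -> MixtureSpec
    lesion: dict  # channel -> MixtureSpec
    lesion_center: tuple[float, float]  # (cx, cy) pixel coords
    lesion_axes: tuple[float, float]  # semi-axes (ax, ay)
    ring_width: float
    rho: float
    seed: int

    def __post_init__(self) -> None:
        for region_name, region in (("skin", self.skin), ("lesion", self.lesion)):
            if set(region) != set(_CHANNELS):
                raise ConfigError(
                    f"{region_name} must map exactly the channels {_CHANNELS}"
                )
        if not (0.0 <= self.rho <= 1.0):
            raise ConfigError(f"rho must be in [0, 1], got {self.rho}")
        cx, cy = self.lesion_center
        ax, ay = self.lesion_axes
        if ax <= 0 or ay <= 0 or self.ring_width <= 0:
            raise ConfigError("lesion axes and ring width must be positive")
        if (
            cx - ax - self.ring_width < 0
            or cx + ax + self.ring_width > self.width - 1
            or cy - ay - self.ring_width < 0
            or cy + ay + self.ring_width > self.height - 1
        ):
            raise ConfigError("lesion ellipse plus perilesional ring must fit inside the image")

    def to_yaml(self, path: Union[str, Path]) -> None:
        d = asdict(self)
        for region in ("skin", "lesion"):
            d[region] = {
                c: [list(comp) for comp in spec["components"]]
                for c, spec in d[region].items()
            }
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "SceneConfig":
        d = yaml.safe_load(Path(path).read_text())
        for region in ("skin", "lesion"):
            d[region] = {
                c: MixtureSpec(tuple(tuple(comp) for comp in comps))
                for c, comps in d[region].items()
            }
        d["lesion_center"] = tuple(d["lesion_center"])
        d["lesion_axes"] = tuple(d["lesion_axes"])
        return cls(**d)


def sample_mixture(
    spec: MixtureSpec, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` 8-bit intensities from a Gaussian mixture.

    Component per draw chosen by weight; value rounded and clipped to
    [0, 255].  Reproducible given the generator's state.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    u = rng.random(n)
    comp = np.searchsorted(np.cumsum(spec.weights), u, side="right")
    comp = np.minimum(comp, len(spec.components) - 1)
    vals = spec.means[comp] + spec.sds[comp] * rng.standard_normal(n)
    return np.clip(np.rint(vals), 0, 255).astype(np.uint8)


def _sample_region(
    region: dict, n: int, rho: float, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Sample coupled R/G/B intensities for ``n`` pixels of one region."""
    u = rng.random(n)  # shared component selector
    z_shared = rng.standard_normal(n)
    out = {}
    for c in _CHANNELS:
        spec: MixtureSpec = region[c]
        comp = np.searchsorted(np.cumsum(spec.weights), u, side="right")
        comp = np.minimum(comp, len(spec.components) - 1)
        z_own = rng.standard_normal(n)
        z = rho * z_shared + math.sqrt(1.0 - rho * rho) * z_own
        vals = spec.means[comp] + spec.sds[comp] * z
        out[c] = np.clip(np.rint(vals), 0, 255).astype(np.uint8)
    return out


def _ellipse_mask(
    shape: tuple[int, int],
    center: tuple[float, float],
    axes: tuple[float, float],
) -> np.ndarray:
    cx, cy = center
    ax, ay = axes
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return ((xx - cx) / ax) ** 2 + ((yy - cy) / ay) ** 2 <= 1.0


def render_scene(cfg: SceneConfig) -> tuple[RGBImage, ROIMask, ROIMask]:
    """Render a scene: image plus lesional and perilesional masks.

    Skin pixels (everything outside the lesion ellipse) are drawn from the
    skin mixtures, lesion pixels from the lesion mixtures, both with the
    configured inter-channel coupling.  The perilesional mask is the skin
    ring between the lesion ellipse and the ellipse grown by ``ring_width``.
    """
    shape = (cfg.height, cfg.width)
    lesion = _ellipse_mask(shape, cfg.lesion_center, cfg.lesion_axes)
    outer = _ellipse_mask(
        shape,
        cfg.lesion_center,
        (cfg.lesion_axes[0] + cfg.ring_width, cfg.lesion_axes[1] + cfg.ring_width),
    )
    ring = outer & ~lesion
    if not lesion.any() or not ring.any():
        raise ConfigError("lesion or perilesional ring selects no pixels")

    rng = np.random.default_rng(cfg.seed)
    planes = {c: np.zeros(shape, dtype=np.uint8) for c in _CHANNELS}
    skin_vals = _sample_region(cfg.skin, int((~lesion).sum()), cfg.rho, rng)
    lesion_vals = _sample_region(cfg.lesion, int(lesion.sum()), cfg.rho, rng)
    for c in _CHANNELS:
        planes[c][~lesion] = skin_vals[c]
        planes[c][lesion] = lesion_vals[c]

    img = RGBImage(red=planes["r"], green=planes["g"], blue=planes["b"])
    return (
        img,
        ROIMask(selected=lesion, label="lesional"),
        ROIMask(selected=ring, label="perilesional"),
    )


# --------------------------------------------------------------------------
# Presets — frozen constants emulating the two chromatic regimes.

_SCENE_GEOMETRY = dict(
    width=160,
    height=160,
    lesion_center=(80.0, 80.0),
    lesion_axes=(45.0, 34.0),
    ring_width=14.0,
)

#: Narrow skin background shared by both presets (lightly pigmented skin).
_SKIN = {
    "r": MixtureSpec(((1.0, 182.0, 6.0),)),
    "g": MixtureSpec(((1.0, 152.0, 6.0),)),
    "b": MixtureSpec(((1.0, 128.0, 6.0),)),
}


def nevus_preset(seed: int) -> SceneConfig:
    """Benign-nevus-like scene: narrow unimodal channels, strong coupling.

    The lesion is uniformly darker than the surrounding skin (single
    component per channel, sd 8) with near-total inter-channel correlation
    (rho 0.95), so channel entropies are nearly equal and all divergence
    metrics sit close to zero.
    """
    return SceneConfig(
        skin=_SKIN,
        lesion={
            "r": MixtureSpec(((1.0, 95.0, 8.0),)),
            "g": MixtureSpec(((1.0, 78.0, 8.0),)),
            "b": MixtureSpec(((1.0, 70.0, 8.0),)),
        },
        rho=0.95,
        seed=seed,
        **_SCENE_GEOMETRY,
    )


def melanoma_preset(seed: int) -> SceneConfig:
    """Melanoma-like scene: broad multimodal channels, weak coupling.

    Three components per channel with channel-specific means and spreads
    (rho 0.3) produce broad, multimodal, decorrelated histograms — large
    inter-channel entropy divergence, i.e. polychromia.
    """
    return SceneConfig(
        skin=_SKIN,
        lesion={
            "r": MixtureSpec(
                ((0.40, 60.0, 18.0), (0.35, 130.0, 22.0), (0.25, 205.0, 15.0))
            ),
            "g": MixtureSpec(
                ((0.55, 85.0, 14.0), (0.30, 140.0, 18.0), (0.15, 190.0, 12.0))
            ),
            "b": MixtureSpec(
                ((0.35, 55.0, 12.0), (0.40, 120.0, 30.0), (0.25, 175.0, 20.0))
            ),
        },
        rho=0.3,
        seed=seed,
        **_SCENE_GEOMETRY,
    )


PRESETS = {"nevus": nevus_preset, "melanoma": melanoma_preset}


def write_scene(
    cfg: SceneConfig, outdir: Union[str, Path]
) -> dict[str, Path]:
    """Render a scene and write image, masks, and config to ``outdir``.

    Writes ``scene.png``, ``lesional_mask.png``, ``perilesional_mask.png``
    and ``scene_config.yaml`` (provenance); returns the paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    img, lesional, perilesional = render_scene(cfg)
    paths = {
        "image": outdir / "scene.png",
        "lesional_mask": outdir / "lesional_mask.png",
        "perilesional_mask": outdir / "perilesional_mask.png",
        "config": outdir / "scene_config.yaml",
    }
    iio.imwrite(paths["image"], img.to_array())
    iio.imwrite(paths["lesional_mask"], lesional.selected.astype(np.uint8) * 255)
    iio.imwrite(
        paths["perilesional_mask"], perilesional.selected.astype(np.uint8) * 255
    )
    cfg.to_yaml(paths["config"])
    return paths
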