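"""Synthetic ground-truth renderer for Q-FISH quantification tests.

Renders multi-channel fluorescence fields with known content: circular
nuclei on the DAPI channel, Gaussian telomere spots of planted amplitude
(the "telomere length") and size inside each nucleus, optional PML spots
a planted subset of which colocalize with telomere spots, plus Gaussian
read noise. The planted geometry and intensities are returned alongside
the images, so detection, intensity recovery and APB colocalization can
be validated against ground truth. These are synthetic scenes, not
reproductions of any real microscope's point-spread behavior.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class RenderConfig:
    shape: tuple[int, int] = (384, 384)
    n_nuclei: int = 4
    nucleus_radius: tuple[float, float] = (35.0, 45.0)
    nucleus_intensity: float = 180.0
    spots_per_nucleus: int = 12
    spot_sigma: float = 1.3
    spot_min_separation: float = 8.0
    spot_amplitude: tuple[float, float] = (400.0, 900.0)
    n_pml_per_nucleus: int = 0
    pml_colocalized_fraction: float = 0.0
    pml_amplitude: float = 600.0
    noise_sd: float = 4.0
    background: float = 10.0
    margin: float = 12.0


@dataclass
class RenderedField:
    dapi: np.ndarray
    telo: np.ndarray
    pml: np.ndarray | None
    nuclei: pd.DataFrame  # nucleus, y, x, radius
    spots: pd.DataFrame  # nucleus, y, x, amplitude, sigma, total_intensity
    pml_spots: pd.DataFrame  # nucleus, y, x, colocalized

    def stack(self) -> np.ndarray:
        """Channels stacked (channel, y, x) in DAPI, telo[, PML] order."""
        channels = [self.dapi, self.telo] + ([self.pml] if self.pml is not None else [])
        return np.stack(channels)


def _add_gaussian(img: np.ndarray, y: float, x: float, amplitude: float, sigma: float) -> float:
    """Accumulate a 2-D Gaussian; returns its (clipped) integrated intensity."""
    r = int(np.ceil(4 * sigma))
    y0, x0 = int(round(y)), int(round(x))
    ys = slice(max(0, y0 - r), min(img.shape[0], y0 + r + 1))
    xs = slice(max(0, x0 - r), min(img.shape[1], x0 + r + 1))
    yy, xx = np.mgrid[ys, xs]
    blob = amplitude * np.exp(-(((yy - y) ** 2 + (xx - x) ** 2) / (2 * sigma**2)))
    img[ys, xs] += blob
    return float(blob.sum())


def _place_nuclei(config: RenderConfig, rng: np.random.Generator) -> pd.DataFrame:
    h, w = config.shape
    rows = []
    attempts = 0
    while len(rows) < config.n_nuclei and attempts < 5000:
        attempts += 1
        radius = rng.uniform(*config.nucleus_radius)
        y = rng.uniform(radius + config.margin, h - radius - config.margin)
        x = rng.uniform(radius + config.margin, w - radius - config.margin)
        if all(np.hypot(y - r["y"], x - r["x"]) > radius + r["radius"] + 8 for r in rows):
            rows.append({"nucleus": len(rows) + 1, "y": y, "x": x, "radius": radius})
    if len(rows) < config.n_nuclei:
        raise ValueError("could not place all nuclei without overlap; reduce n_nuclei or radius")
    return pd.DataFrame(rows)


def render_field(config: RenderConfig, seed: int | np.random.Generator = 0) -> RenderedField:
    """Render one synthetic multi-channel field with ground truth."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    h, w = config.shape
    dapi = np.full((h, w), config.background, dtype=float)
    telo = np.full((h, w), config.background, dtype=float)
    pml = np.full((h, w), config.background, dtype=float) if config.n_pml_per_nucleus else None

    nuclei = _place_nuclei(config, rng)
    yy, xx = np.mgrid[0:h, 0:w]
    for row in nuclei.itertuples():
        inside = (yy - row.y) ** 2 + (xx - row.x) ** 2 <= row.radius**2
        dapi[inside] += config.nucleus_intensity

    spot_rows, pml_rows = [], []
    for row in nuclei.itertuples():
        placed: list[tuple[float, float]] = []
        for _ in range(config.spots_per_nucleus):
            # rejection-sample so rendered spots stay resolvable as separate objects
            for _attempt in range(2000):
                rr = row.radius * 0.85 * np.sqrt(rng.uniform())
                theta = rng.uniform(0, 2 * np.pi)
                sy, sx = row.y + rr * np.sin(theta), row.x + rr * np.cos(theta)
                if all(np.hypot(sy - py, sx - px) >= config.spot_min_separation for py, px in placed):
                    break
            else:
                raise ValueError("could not place spots with the requested separation")
            placed.append((sy, sx))
            amp = rng.uniform(*config.spot_amplitude)
            total = _add_gaussian(telo, sy, sx, amp, config.spot_sigma)
            spot_rows.append(
                {"nucleus": row.nucleus, "y": sy, "x": sx, "amplitude": amp,
                 "sigma": config.spot_sigma, "total_intensity": total}
            )
        for _ in range(config.n_pml_per_nucleus):
            mine = [s for s in spot_rows if s["nucleus"] == row.nucleus]
            colocalized = bool(rng.uniform() < config.pml_colocalized_fraction) and bool(mine)
            if colocalized:
                target = mine[int(rng.integers(0, len(mine)))]
                py = target["y"] + rng.uniform(-1.0, 1.0)
                px = target["x"] + rng.uniform(-1.0, 1.0)
            else:
                rr = row.radius * 0.8 * np.sqrt(rng.uniform())
                theta = rng.uniform(0, 2 * np.pi)
                py, px = row.y + rr * np.sin(theta), row.x + rr * np.cos(theta)
            _add_gaussian(pml, py, px, config.pml_amplitude, config.spot_sigma)
            pml_rows.append({"nucleus": row.nucleus, "y": py, "x": px, "colocalized": bool(colocalized)})

    for img in filter(lambda a: a is not None, (dapi, telo, pml)):
        img += rng.normal(0.0, config.noise_sd, size=img.shape)
        np.clip(img, 0.0, None, out=img)

    return RenderedField(
        dapi=dapi,
        telo=telo,
        pml=pml,
        nuclei=nuclei,
        spots=pd.DataFrame(spot_rows, columns=["nucleus", "y", "x", "amplitude", "sigma", "total_intensity"]),
        pml_spots=pd.DataFrame(pml_rows, columns=["nucleus", "y", "x", "colocalized"]),
    )
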