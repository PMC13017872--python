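"""Synthetic data with known ground truth for every pipeline stage.

Two generators:

* :func:`simulate_clonogenic` draws colony-count tables under the
  linear-quadratic survival law.  Counts are binomial thinnings of the
  seeded cells, colonies ~ Binomial(N, pe0 * SF(D)), so a dish can never
  form more colonies than cells were seeded — the physical bound a
  Poisson model would violate.
* :func:`generate_image_pair` renders a DAPI / focus-channel image pair:
  elliptical nuclei with a smooth interior profile, 2-D Gaussian foci
  inside nuclei, small peri-nuclear micronucleus discs, and additive
  Gaussian background noise, together with a ground-truth table of every
  planted object.

Both are pure functions of (config, seed): the same configuration and
seed reproduce the same tables and rasters bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from . import dosimetry
from .clonogenic import ColonyRecord
from .dosimetry import AG111, ExposurePlan, RadionuclidePhysics, plan_exposure

__all__ = [
    "ClonogenicSimConfig",
    "ImageSimConfig",
    "simulate_clonogenic",
    "generate_image_pair",
    "generate_exposure_dataset",
]


@dataclass(frozen=True)
class ClonogenicSimConfig:
    """Design of a simulated colony-formation experiment.

    Defaults reproduce the study design: four doses spanning 0.5-4 Gy,
    triplicate dishes, 1000 cells seeded per dish, and a control plating
    efficiency of 0.5.
    """

    alpha: float = 0.5            # Gy⁻¹
    beta: float = 0.04            # Gy⁻²
    doses_gy: tuple[float, ...] = (0.5, 1.0, 2.0, 4.0)
    cells_seeded: int = 1000
    pe0: float = 0.5              # control plating efficiency
    replicates: int = 3
    exposure_days: float = 6.0
    cell_line: str = "synthetic"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.pe0 <= 1:
            raise ValueError("pe0 must be in (0, 1]")
        if self.replicates < 1:
            raise ValueError("need at least one replicate")
        for d in self.doses_gy:
            if self.pe0 * self.survival(d) > 1:
                raise ValueError(f"pe0 * SF({d} Gy) exceeds 1")

    def survival(self, dose_gy: float) -> float:
        return math.exp(-(self.alpha * dose_gy + self.beta * dose_gy ** 2))


def simulate_clonogenic(config: ClonogenicSimConfig,
                        noise_free: bool = False) -> list[ColonyRecord]:
    """Simulate one clonogenic experiment, controls included.

    With ``noise_free=True`` the binomial sampling is replaced by the
    expected count on a very large virtual dish (10^7 cells), so the
    integer rounding is negligible and downstream fits recover the
    generating parameters to numerical precision.
    """
    rng = np.random.default_rng(config.seed)
    records: list[ColonyRecord] = []

    def make_dish(dose: float, rep: int, is_control: bool) -> ColonyRecord:
        p = config.pe0 * config.survival(dose)
        if noise_free:
            n = 10_000_000
            colonies = int(round(n * p))
        else:
            n = config.cells_seeded
            colonies = int(rng.binomial(n, p))
        tag = "control" if is_control else f"{dose:g}Gy"
        return ColonyRecord(
            sample_id=f"{config.cell_line}_{config.exposure_days:g}d_{tag}_r{rep}",
            dose_gy=dose, exposure_days=config.exposure_days,
            cells_seeded=n, colonies=colonies, is_control=is_control,
            replicate=rep, cell_line=config.cell_line)

    for rep in range(1, config.replicates + 1):
        records.append(make_dish(0.0, rep, True))
    for dose in config.doses_gy:
        for rep in range(1, config.replicates + 1):
            records.append(make_dish(dose, rep, False))
    return records


@dataclass(frozen=True)
class ImageSimConfig:
    """Layout of a synthetic two-channel fluorescence field.

    Nuclei are non-overlapping ellipses (random orientation, semi-axes
    drawn from ``nucleus_semi_axes``); foci are isotropic 2-D Gaussians
    planted well inside their nucleus with a minimum mutual separation so
    that planted counts are resolvable by construction; micronuclei are
    small discs a few pixels outside the nuclear boundary of an exact
    fraction ``mn_frequency`` of the nuclei.  Intensities are arbitrary
    fluorescence units with additive Gaussian noise of SD ``noise_sd``.
    """

    n_nuclei: int = 40
    image_size: tuple[int, int] = (512, 512)
    nucleus_semi_axes: tuple[float, float] = (10.0, 15.0)  # px, range of both axes
    nucleus_amplitude: float = 1.0
    foci_per_nucleus: int | float = 0      # fixed k (int) or Poisson mean (float)
    foci_poisson: bool = False
    focus_amplitude: float = 10.0          # multiples of noise_sd
    focus_sigma: float = 1.5               # px
    focus_min_separation: float = 6.0      # px between planted foci
    nuclear_background: float = 1.0        # focus-channel interior level, x noise_sd
    mn_frequency: float = 0.0              # fraction of nuclei given one micronucleus
    mn_radius: float = 3.0                 # px
    mn_gap: float = 4.0                    # px between nucleus edge and micronucleus
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nuclei < 0 or self.focus_amplitude <= 0:
            raise ValueError("counts must be >= 0 and amplitudes positive")
        if not 0 <= self.mn_frequency <= 1:
            raise ValueError("mn_frequency must be in [0, 1]")


@dataclass
class ImageGroundTruth:
    nuclei: pd.DataFrame       # label, row, col, a, b, theta, n_foci, has_mn
    foci: pd.DataFrame         # nucleus_label, row, col
    micronuclei: pd.DataFrame  # nucleus_label, row, col, radius


def _place_nuclei(cfg: ImageSimConfig, rng: np.random.Generator) -> list[dict]:
    h, w = cfg.image_size
    lo, hi = cfg.nucleus_semi_axes
    placed: list[dict] = []
    margin = hi + cfg.mn_radius + cfg.mn_gap + 4
    attempts = 0
    max_attempts = 300 * max(cfg.n_nuclei, 1)
    while len(placed) < cfg.n_nuclei:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"could not pack {cfg.n_nuclei} nuclei into {cfg.image_size}: "
                f"placed {len(placed)}")
        a, b = sorted(rng.uniform(lo, hi, size=2), reverse=True)
        r = rng.uniform(margin, h - margin)
        c = rng.uniform(margin, w - margin)
        # keep centres far enough apart that ellipses plus the micronucleus
        # annulus never overlap
        if all(math.hypot(r - p["row"], c - p["col"])
               > (a + p["a"] + 2 * (cfg.mn_radius + cfg.mn_gap) + 2)
               for p in placed):
            placed.append({"label": len(placed) + 1, "row": r, "col": c,
                           "a": a, "b": b, "theta": rng.uniform(0, math.pi)})
    return placed


def _ellipse_interior(shape: tuple[int, int], nuc: dict,
                      shrink: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    rr, cc = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]),
                         indexing="ij", sparse=True)
    ct, st = math.cos(nuc["theta"]), math.sin(nuc["theta"])
    x = (rr - nuc["row"]) * ct + (cc - nuc["col"]) * st
    y = -(rr - nuc["row"]) * st + (cc - nuc["col"]) * ct
    q = (x / (nuc["a"] * shrink)) ** 2 + (y / (nuc["b"] * shrink)) ** 2
    return q, q <= 1.0


def _place_foci(nuc: dict, k: int, cfg: ImageSimConfig,
                rng: np.random.Generator) -> list[tuple[float, float]]:
    """Plant ``k`` focus centres inside the 70%-shrunk ellipse with
    pairwise separation >= ``focus_min_separation``.

    Rejection sampling first; if the nucleus is too crowded for random
    placement, fall back to a randomly rotated centre-plus-ring template
    (exact minimum separation by construction, up to 7 foci for the
    default nucleus sizes)."""
    ct, st = math.cos(nuc["theta"]), math.sin(nuc["theta"])

    def to_image(xa: float, yb: float) -> tuple[float, float]:
        return (nuc["row"] + xa * ct - yb * st,
                nuc["col"] + xa * st + yb * ct)

    shrink = 0.7
    pts: list[tuple[float, float]] = []
    for _ in range(400 * max(k, 1)):
        if len(pts) == k:
            return pts
        u, ang = rng.uniform(0, 1), rng.uniform(0, 2 * math.pi)
        xa = math.sqrt(u) * math.cos(ang) * nuc["a"] * shrink
        yb = math.sqrt(u) * math.sin(ang) * nuc["b"] * shrink
        fr, fc = to_image(xa, yb)
        if all(math.hypot(fr - pr, fc - pc) >= cfg.focus_min_separation
               for pr, pc in pts):
            pts.append((fr, fc))
    if len(pts) == k:
        return pts

    # ring template: centre + up to 6 points at radius = min separation
    r = cfg.focus_min_separation
    if k > 7 or r > shrink * min(nuc["a"], nuc["b"]):
        raise RuntimeError(
            f"could not place {k} separated foci in nucleus {nuc['label']}: "
            f"placed {len(pts)} by sampling and the ring fallback needs "
            f"k <= 7 and separation within the nucleus")
    phase = rng.uniform(0, 2 * math.pi)
    pts = [to_image(0.0, 0.0)]
    for i in range(k - 1):
        ang = phase + 2 * math.pi * i / 6.0
        pts.append(to_image(r * math.cos(ang), r * math.sin(ang)))
    return pts


def generate_image_pair(cfg: ImageSimConfig
                        ) -> tuple[np.ndarray, np.ndarray, ImageGroundTruth]:
    """Render a (DAPI, focus-channel) image pair plus ground truth.

    Every planted focus lies strictly inside its nucleus; every planted
    micronucleus disc lies outside all nuclei within ``mn_gap`` pixels of
    its parent's boundary.  Raises if the requested number of nuclei
    cannot be packed.
    """
    rng = np.random.default_rng(cfg.seed)
    h, w = cfg.image_size
    dapi = np.zeros((h, w), dtype=float)
    focus = np.zeros((h, w), dtype=float)

    nuclei = _place_nuclei(cfg, rng)
    foci_rows: list[dict] = []
    mn_rows: list[dict] = []

    for nuc in nuclei:
        q, inside = _ellipse_interior((h, w), nuc)
        # smooth dome profile, brightest at the centre
        dapi[inside] += cfg.nucleus_amplitude * (1.0 - 0.3 * q[inside])
        focus[inside] += cfg.nuclear_background * cfg.noise_sd

        if cfg.foci_poisson:
            k = int(rng.poisson(float(cfg.foci_per_nucleus)))
        else:
            k = int(cfg.foci_per_nucleus)
        pts = _place_foci(nuc, k, cfg, rng)
        nuc["n_foci"] = k
        for fr, fc in pts:
            foci_rows.append({"nucleus_label": nuc["label"], "row": fr, "col": fc})
            _add_gaussian_spot(focus, fr, fc, cfg.focus_sigma,
                               cfg.focus_amplitude * cfg.noise_sd)

    n_mn = int(round(cfg.mn_frequency * len(nuclei)))
    mn_hosts = rng.choice(len(nuclei), size=n_mn, replace=False) if n_mn else []
    for idx in mn_hosts:
        nuc = nuclei[idx]
        ang = rng.uniform(0, 2 * math.pi)
        # radius of the ellipse in direction ang (in the nucleus frame)
        ct, st = math.cos(nuc["theta"]), math.sin(nuc["theta"])
        ca, sa = math.cos(ang), math.sin(ang)
        edge = 1.0 / math.sqrt((ca / nuc["a"]) ** 2 + (sa / nuc["b"]) ** 2)
        d = edge + cfg.mn_gap + cfg.mn_radius
        mr = nuc["row"] + d * (ca * ct - sa * st)
        mc = nuc["col"] + d * (ca * st + sa * ct)
        _add_disc(dapi, mr, mc, cfg.mn_radius, cfg.nucleus_amplitude)
        mn_rows.append({"nucleus_label": nuc["label"], "row": mr, "col": mc,
                        "radius": cfg.mn_radius})
    has_mn = {r["nucleus_label"] for r in mn_rows}

    dapi += rng.normal(0.0, cfg.noise_sd, size=(h, w))
    focus += rng.normal(0.0, cfg.noise_sd, size=(h, w))

    truth = ImageGroundTruth(
        nuclei=pd.DataFrame([{**{k: n[k] for k in
                                 ("label", "row", "col", "a", "b", "theta")},
                              "n_foci": n.get("n_foci", 0),
                              "has_mn": n["label"] in has_mn}
                             for n in nuclei],
                            columns=["label", "row", "col", "a", "b",
                                     "theta", "n_foci", "has_mn"]),
        foci=pd.DataFrame(foci_rows, columns=["nucleus_label", "row", "col"]),
        micronuclei=pd.DataFrame(mn_rows, columns=["nucleus_label", "row",
                                                   "col", "radius"]),
    )
    return dapi, focus, truth


def _add_gaussian_spot(img: np.ndarray, row: float, col: float,
                       sigma: float, amplitude: float) -> None:
    r0, r1 = int(max(0, row - 5 * sigma)), int(min(img.shape[0], row + 5 * sigma + 1))
    c0, c1 = int(max(0, col - 5 * sigma)), int(min(img.shape[1], col + 5 * sigma + 1))
    rr, cc = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1),
                         indexing="ij", sparse=True)
    img[r0:r1, c0:c1] += amplitude * np.exp(
        -((rr - row) ** 2 + (cc - col) ** 2) / (2.0 * sigma ** 2))


def _add_disc(img: np.ndarray, row: float, col: float, radius: float,
              amplitude: float) -> None:
    r0, r1 = int(max(0, row - radius - 2)), int(min(img.shape[0], row + radius + 3))
    c0, c1 = int(max(0, col - radius - 2)), int(min(img.shape[1], col + radius + 3))
    rr, cc = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1),
                         indexing="ij", sparse=True)
    inside = (rr - row) ** 2 + (cc - col) ** 2 <= radius ** 2
    img[r0:r1, c0:c1][inside] += amplitude


def generate_exposure_dataset(
        doses_gy: Sequence[float] = (0.5, 1.0, 2.0, 4.0),
        exposure_days: Sequence[float] = (4.0, 6.0),
        arm_params: dict[float, tuple[float, float]] | None = None,
        s_medium: float | None = None,
        physics: RadionuclidePhysics = AG111,
        base_config: ClonogenicSimConfig = ClonogenicSimConfig(),
        seed: int = 0,
) -> tuple[list[ExposurePlan], dict[float, list[ColonyRecord]]]:
    """Produce matched exposure plans and simulated colony tables for a
    multi-arm experiment (one arm per exposure time).

    ``arm_params`` maps exposure time -> (alpha, beta) truth per arm;
    arms default to the base configuration's parameters.  Each arm gets
    an independent child seed derived from ``seed``.
    """
    if s_medium is None:
        s_medium = dosimetry.S_MEDIUM_CALIBRATED
    plans = [plan_exposure(doses_gy, t, s_medium, physics)
             for t in exposure_days]
    tables: dict[float, list[ColonyRecord]] = {}
    child_seeds = np.random.SeedSequence(seed).spawn(len(exposure_days))
    for t, ss in zip(exposure_days, child_seeds):
        alpha, beta = (arm_params or {}).get(
            t, (base_config.alpha, base_config.beta))
        cfg = replace(base_config, alpha=alpha, beta=beta, exposure_days=t,
                      doses_gy=tuple(doses_gy),
                      seed=int(ss.generate_state(1)[0] % (2 ** 31)))
        tables[t] = simulate_clonogenic(cfg)
    return plans, tables
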