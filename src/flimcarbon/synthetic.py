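"""Synthetic TCSPC and FLIM data with known ground truth.

Stands in for the microscope: Gaussian IRFs at a chosen FWHM, Poisson-noise
solution decays from any multi-exponential model, the four-mixture
two-enzyme series, and two-channel cell scenes (NAD(P)H FLIM stack + FAD
intensity image + label masks) with per-cell parameters drawn from stated
distributions.  Every generated object carries a ground-truth record, and
everything is reproducible from a single integer seed.

Photon noise is Poisson only (TCSPC shot noise); detector afterpulsing,
dead time and pile-up are not modeled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .binding import mixture_table
from .decay_model import IRF, DecayHistogram, MultiExpModel, TimeAxis, evaluate_model
from .experiments import UNMIX_LIFETIMES_NS

__all__ = [
    "TABLE1_LDH_UM",
    "TABLE1_MDH_UM",
    "TABLE1_FREE_FRACTION",
    "DEFAULT_SOLUTION_PHOTONS",
    "SceneSpec",
    "GroundTruth",
    "make_irf",
    "table1_design",
    "simulate_solution_decay",
    "simulate_mixture_series",
    "simulate_cell_scene",
]

#: The published two-enzyme mixture design: [LDH] and [MDH] in uM, and the
#: measured free-NADH amplitude fraction of each mixture.
TABLE1_LDH_UM = (4.9, 14.2, 1.4, 10.0)
TABLE1_MDH_UM = (13.0, 2.6, 13.0, 8.0)
TABLE1_FREE_FRACTION = (0.605, 0.480, 0.689, 0.426)

#: Default photon budget for whole-solution decays; puts the peak bin well
#: above the 3000-count solution quality gate for lifetimes up to ~2.5 ns.
DEFAULT_SOLUTION_PHOTONS = 5e5
#: Default IRF width.
DEFAULT_IRF_FWHM_PS = 220.0

_PS_PER_NS = 1000.0


@dataclass
class GroundTruth:
    """Truth record accompanying every synthetic object."""

    seed: int
    config: dict = field(default_factory=dict)
    cells: pd.DataFrame | None = None
    mixtures: pd.DataFrame | None = None


@dataclass
class SceneSpec:
    """Parameters of a synthetic two-channel cell scene.

    Cells are non-overlapping ellipses with concentric elliptical nuclei.
    Per-cell decay parameters are drawn from truncated normal distributions
    whose defaults sit inside reported cellular ranges (bound lifetime
    ~2.4-2.9 ns); they are plausible stand-ins, not measured values.
    Budgets are expected photons per pixel over the whole decay.
    """

    shape: tuple[int, int] = (256, 256)
    n_cells: int = 20
    cell_radius_px: tuple[float, float] = (8.0, 14.0)
    nucleus_scale: float = 0.45
    alpha1_mean: float = 0.75
    alpha1_sd: float = 0.03
    tau1_mean_ns: float = 0.6
    tau1_sd_ns: float = 0.1
    tau2_mean_ns: float = 2.7
    tau2_sd_ns: float = 0.2
    redox_mean: float = 1.0
    redox_sd: float = 0.1
    cytoplasm_photons: float = 150.0
    nucleus_photons: float = 50.0
    background_photons: float = 0.5
    seed: int = 0
    max_place_attempts: int = 2000


def make_irf(
    fwhm_ps: float = DEFAULT_IRF_FWHM_PS,
    axis: TimeAxis | None = None,
    peak_fraction: float = 0.1,
) -> IRF:
    """Discrete Gaussian IRF, unit sum, peaked at ``peak_fraction`` of the window.

    The requested FWHM (ps) is reproduced by the sampled curve to within a
    bin width.
    """
    if axis is None:
        axis = TimeAxis()
    fwhm_ns = fwhm_ps / _PS_PER_NS
    if fwhm_ns >= axis.window / 4:
        raise ValueError(
            f"IRF FWHM {fwhm_ps} ps too large for a {axis.window} ns window"
        )
    sigma = fwhm_ns / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    center = peak_fraction * axis.window
    t = axis.times
    counts = np.exp(-0.5 * ((t - center) / sigma) ** 2)
    counts /= counts.sum()
    return IRF(counts=counts, axis=axis, fwhm_ps=fwhm_ps)


def table1_design() -> pd.DataFrame:
    """The published four-mixture design with measured free fractions attached."""
    table = mixture_table(TABLE1_LDH_UM, TABLE1_MDH_UM)
    table["free_fraction"] = TABLE1_FREE_FRACTION
    return table


def simulate_solution_decay(
    model: MultiExpModel,
    irf: IRF,
    photons: float = DEFAULT_SOLUTION_PHOTONS,
    seed: int = 0,
) -> tuple[DecayHistogram, GroundTruth]:
    """Poisson draw around the reconvolution-model expectation.

    ``photons`` is the expected signal total over the decay window
    (background from ``model.background`` adds on top).
    """
    if photons <= 0:
        raise ValueError("photon budget must be > 0")
    expected = evaluate_model(model, irf, irf.axis, amplitude_scale=photons)
    rng = np.random.default_rng(seed)
    counts = rng.poisson(expected)
    hist = DecayHistogram(counts=counts, axis=irf.axis, meta={"seed": seed})
    truth = GroundTruth(
        seed=seed,
        config={
            "alphas": model.alphas.tolist(),
            "taus_ns": model.taus.tolist(),
            "background": model.background,
            "photons": photons,
        },
    )
    return hist, truth


def mixture_truth_amplitudes(
    free_fraction: float, ldh_fraction: float
) -> tuple[float, float, float]:
    """Ground-truth amplitude triple (free, MDH-bound, LDH-bound) for a mixture.

    The bound amplitude 1 - free is split between the two enzymes in
    proportion to the LDH concentration fraction — the proportionality the
    through-origin regression validates.
    """
    if not 0 <= free_fraction <= 1 or not 0 <= ldh_fraction <= 1:
        raise ValueError("fractions must be in [0, 1]")
    bound = 1.0 - free_fraction
    return (free_fraction, bound * (1.0 - ldh_fraction), bound * ldh_fraction)


def simulate_mixture_series(
    design: pd.DataFrame | None = None,
    irf: IRF | None = None,
    photons: float = DEFAULT_SOLUTION_PHOTONS,
    replicates: int = 3,
    seed: int = 0,
    lifetimes_ns: tuple[float, float, float] = UNMIX_LIFETIMES_NS,
) -> tuple[list[tuple[float, DecayHistogram]], GroundTruth]:
    """Simulate the two-enzyme mixture series with known amplitude triples.

    ``design`` needs ``ldh_fraction`` and ``free_fraction`` columns (default:
    the published four-mixture design).  Each mixture is drawn ``replicates``
    times with distinct sub-seeds; the returned decays are labeled with the
    true LDH concentration fraction, and the truth table records the
    amplitude triple of every replicate.
    """
    if design is None:
        design = table1_design()
    if len(design) < 2:
        raise ValueError("design needs at least 2 mixtures")
    if irf is None:
        irf = make_irf()
    decays: list[tuple[float, DecayHistogram]] = []
    truth_rows = []
    sub = 0
    for _, row in design.iterrows():
        alphas = mixture_truth_amplitudes(row["free_fraction"], row["ldh_fraction"])
        model = MultiExpModel.from_arrays(alphas, lifetimes_ns)
        for rep in range(replicates):
            rep_seed = (seed * 10_000 + sub) % (2**31 - 1)
            sub += 1
            hist, _ = simulate_solution_decay(model, irf, photons, seed=rep_seed)
            decays.append((float(row["ldh_fraction"]), hist))
            truth_rows.append(
                {
                    "mixture": row.get("mixture", "?"),
                    "replicate": rep,
                    "seed": rep_seed,
                    "ldh_fraction": row["ldh_fraction"],
                    "alpha_free": alphas[0],
                    "alpha_mdh": alphas[1],
                    "alpha_ldh": alphas[2],
                }
            )
    truth = GroundTruth(
        seed=seed,
        config={"photons": photons, "lifetimes_ns": list(lifetimes_ns)},
        mixtures=pd.DataFrame(truth_rows),
    )
    return decays, truth


def _truncated_normal(rng, mean, sd, lo, hi):
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return x
    return float(np.clip(mean, lo, hi))


def _place_cells(rng, spec: SceneSpec):
    """Rejection-sample non-overlapping ellipse geometries."""
    rows, cols = spec.shape
    placed = []  # (cy, cx, a, b, theta)
    attempts = 0
    while len(placed) < spec.n_cells:
        if attempts >= spec.max_place_attempts:
            raise RuntimeError(
                f"could not place {spec.n_cells} non-overlapping cells in "
                f"{spec.shape} after {attempts} attempts; reduce n_cells or "
                "try another seed"
            )
        attempts += 1
        a = rng.uniform(*spec.cell_radius_px)
        b = rng.uniform(*spec.cell_radius_px)
        r = max(a, b)
        cy = rng.uniform(r + 1, rows - r - 1)
        cx = rng.uniform(r + 1, cols - r - 1)
        if any(
            np.hypot(cy - py, cx - px) < r + max(pa, pb) + 1
            for py, px, pa, pb, _ in placed
        ):
            continue
        placed.append((cy, cx, a, b, rng.uniform(0, np.pi)))
    return placed


def _ellipse_mask(shape, cy, cx, a, b, theta) -> np.ndarray:
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    dy, dx = yy - cy, xx - cx
    u = dx * np.cos(theta) + dy * np.sin(theta)
    v = -dx * np.sin(theta) + dy * np.cos(theta)
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def simulate_cell_scene(spec: SceneSpec, irf: IRF | None = None):
    """Generate a two-channel cell scene with ground truth.

    Returns ``(nadph_stack, fad_intensity, masks, truth)`` where
    ``nadph_stack`` is a (rows, cols, n_bins) photon-count array, the FAD
    channel is a 2-D intensity image scaled so each cell's cytoplasm redox
    ratio matches its drawn truth in expectation, and ``masks`` carries cell
    and nucleus labels (nucleus strictly inside its cell).  Imports of the
    container types are deferred to avoid a cycle with :mod:`.imaging`.
    """
    from .imaging import FlimImage, LabelMasks

    if irf is None:
        irf = make_irf()
    axis = irf.axis
    rng = np.random.default_rng(spec.seed)
    rows, cols = spec.shape
    placed = _place_cells(rng, spec)

    cell_labels = np.zeros(spec.shape, dtype=np.uint16)
    nucleus_labels = np.zeros(spec.shape, dtype=np.uint16)
    expected_nadph = np.zeros((rows, cols, axis.n_bins))
    truth_rows = []
    expected_total = 0.0

    for lab, (cy, cx, a, b, theta) in enumerate(placed, start=1):
        cell = _ellipse_mask(spec.shape, cy, cx, a, b, theta)
        nucleus = _ellipse_mask(
            spec.shape, cy, cx, a * spec.nucleus_scale, b * spec.nucleus_scale, theta
        ) & cell
        cell_labels[cell] = lab
        nucleus_labels[nucleus] = lab

        alpha1 = _truncated_normal(rng, spec.alpha1_mean, spec.alpha1_sd, 0.0, 1.0)
        tau1 = _truncated_normal(rng, spec.tau1_mean_ns, spec.tau1_sd_ns, 0.1, 10.0)
        tau2 = _truncated_normal(rng, spec.tau2_mean_ns, spec.tau2_sd_ns, 0.5, 10.0)
        redox = _truncated_normal(rng, spec.redox_mean, spec.redox_sd, 0.05, 10.0)
        model = MultiExpModel.from_arrays([alpha1, 1.0 - alpha1], [tau1, tau2])

        cyto_curve = evaluate_model(model, irf, axis, spec.cytoplasm_photons)
        nuc_curve = evaluate_model(model, irf, axis, spec.nucleus_photons)
        cyto = cell & ~nucleus
        expected_nadph[cyto] = cyto_curve
        expected_nadph[nucleus] = nuc_curve
        expected_total += cyto.sum() * spec.cytoplasm_photons
        expected_total += nucleus.sum() * spec.nucleus_photons
        truth_rows.append(
            {
                "cell": lab,
                "alpha1": alpha1,
                "tau1_ns": tau1,
                "tau2_ns": tau2,
                "tau_m_ns": alpha1 * tau1 + (1 - alpha1) * tau2,
                "redox_ratio": redox,
                "n_cytoplasm_px": int(cyto.sum()),
            }
        )

    background = cell_labels == 0
    if spec.background_photons > 0:
        bg_curve = np.full(axis.n_bins, spec.background_photons / axis.n_bins)
        expected_nadph[background] = bg_curve
        expected_total += background.sum() * spec.background_photons

    nadph_counts = rng.poisson(expected_nadph).astype(np.uint16)

    # FAD channel: per-pixel expected intensity = NAD(P)H expected intensity
    # divided by the cell's redox ratio
    expected_intensity = expected_nadph.sum(axis=2)
    fad_expected = np.zeros(spec.shape)
    for row_t in truth_rows:
        sel = cell_labels == row_t["cell"]
        fad_expected[sel] = expected_intensity[sel] / row_t["redox_ratio"]
    fad_expected[background] = expected_intensity[background]
    fad = rng.poisson(fad_expected).astype(np.uint16)

    nadph = FlimImage(counts=nadph_counts, axis=axis, channel="NADPH")
    masks = LabelMasks(cell_labels=cell_labels, nucleus_labels=nucleus_labels)
    truth = GroundTruth(
        seed=spec.seed,
        config={
            "shape": list(spec.shape),
            "n_cells": spec.n_cells,
            "cytoplasm_photons": spec.cytoplasm_photons,
            "expected_total_photons": expected_total,
        },
        cells=pd.DataFrame(truth_rows),
    )
    return nadph, fad, masks, truth
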