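"""Seeded synthetic-data generators for every pipeline stage.

No raw images or event files are published for the pilot cohort, so each
imaging and cytometry stage is validated on synthetic inputs whose ground
truth is known in closed form:

* CT phantoms — an ellipsoidal brain inside a hyperdense skull shell,
  with a hyperdense (blood-window) hematoma ellipsoid and a hypodense
  edema shell around it; all compartment volumes have analytic values.
* Blood smears — round nuclei are disks (circularity 1); NET-like nuclei
  are star polygons whose outer radius fixes the minimum enclosing
  circle and whose spike depth fixes the analytic perimeter, so each
  carries an exact target circularity.
* Flow events — Gaussian scatter clouds for neutrophils, monocytes and
  lymphocytes with a planted double-positive fraction among neutrophils,
  plus isotype-control events from a stated background distribution.
* Cohorts — Gaussian-copula draws with a target Spearman correlation
  structure and configurable marginal families.

Every generator is a pure function of its spec (seed included).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.draw import disk as draw_disk
from skimage.draw import polygon as draw_polygon

from .cohort import CohortTable
from .errors import SpecError
from .netquant import SmearImage
from .volumetry import CTVolume

# ------------------------------------------------------------- CT phantom


@dataclass
class PhantomSpec:
    """Geometry and HU statistics of a head-CT phantom.

    Centers and semi-axes are in mm relative to the grid origin; the
    edema shell extends the hematoma semi-axes by ``edema_thickness_mm``.
    """

    shape: tuple[int, int, int] = (80, 96, 96)
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    brain_center: tuple[float, float, float] = (40.0, 48.0, 48.0)
    brain_axes: tuple[float, float, float] = (34.0, 42.0, 42.0)
    brain_hu: float = 30.0
    skull_thickness_mm: float = 4.0
    skull_hu: float = 1000.0
    air_hu: float = -1000.0
    hematoma_center: tuple[float, float, float] = (40.0, 48.0, 48.0)
    hematoma_axes: tuple[float, float, float] = (10.0, 12.0, 14.0)
    hematoma_hu: float = 60.0
    edema_thickness_mm: float = 6.0
    edema_hu: float = 15.0
    noise_sd: float = 3.0
    seed: int = 0


def _ellipsoid_mask(shape, voxel_size, center, axes) -> np.ndarray:
    grids = np.meshgrid(*[np.arange(s) * v for s, v in zip(shape, voxel_size)],
                        indexing="ij")
    q = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, axes))
    return q <= 1.0


def _ellipsoid_volume_ml(axes) -> float:
    return 4.0 / 3.0 * math.pi * axes[0] * axes[1] * axes[2] / 1000.0


def generate_ct_phantom(spec: PhantomSpec
                        ) -> tuple[CTVolume, dict[str, np.ndarray],
                                   dict[str, float]]:
    """Build a phantom CT plus ground-truth masks and analytic volumes (ml).

    Returns ``(volume, masks, analytic)`` with masks ``brain``,
    ``hematoma``, ``edema`` and analytic volumes for each (shell volume =
    outer ellipsoid - hematoma).  Raises :class:`SpecError` when the
    edema shell is not strictly inside the brain.
    """
    outer_axes = tuple(a + spec.edema_thickness_mm for a in spec.hematoma_axes)
    # strict containment check: outer ellipsoid inside brain ellipsoid
    for i in range(3):
        off = abs(spec.hematoma_center[i] - spec.brain_center[i])
        if off + outer_axes[i] >= spec.brain_axes[i]:
            raise SpecError("hematoma + edema shell must sit strictly "
                            "inside the brain ellipsoid")
    shape, vs = spec.shape, spec.voxel_size
    brain = _ellipsoid_mask(shape, vs, spec.brain_center, spec.brain_axes)
    skull_outer = _ellipsoid_mask(
        shape, vs, spec.brain_center,
        tuple(a + spec.skull_thickness_mm for a in spec.brain_axes))
    skull = skull_outer & ~brain
    hematoma = _ellipsoid_mask(shape, vs, spec.hematoma_center,
                               spec.hematoma_axes)
    edema = _ellipsoid_mask(shape, vs, spec.hematoma_center,
                            outer_axes) & ~hematoma
    hu = np.full(shape, spec.air_hu, dtype=float)
    hu[brain] = spec.brain_hu
    hu[skull] = spec.skull_hu
    hu[edema] = spec.edema_hu
    hu[hematoma] = spec.hematoma_hu
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        hu += rng.normal(0.0, spec.noise_sd, size=shape)
    analytic = {
        "brain": _ellipsoid_volume_ml(spec.brain_axes),
        "hematoma": _ellipsoid_volume_ml(spec.hematoma_axes),
        "edema": (_ellipsoid_volume_ml(outer_axes)
                  - _ellipsoid_volume_ml(spec.hematoma_axes)),
    }
    masks = {"brain": brain, "hematoma": hematoma, "edema": edema}
    return CTVolume(values=hu, voxel_size=vs), masks, analytic


# ----------------------------------------------------------------- smears


@dataclass
class SmearSpec:
    """Layout and intensity statistics of synthetic smear fields."""

    n_fields: int = 10
    cells_per_field: int = 12
    net_fraction: float = 0.2
    double_positive_fraction: float = 1.0
    nucleus_radius_um: float = 5.0
    star_points: int = 6
    target_net_circularity: float = 0.6
    pixel_size: float = 0.25          # μm/px
    field_shape: tuple[int, int] = (512, 512)
    dapi_mean: float = 200.0
    marker_mean: float = 150.0
    background_sd: float = 2.0
    seed: int = 0


def star_polygon(center: tuple[float, float], outer_r: float, inner_r: float,
                 k: int, phase: float = 0.0) -> np.ndarray:
    """Vertices (row, col) of a 2k-gon star with alternating radii."""
    angles = phase + np.arange(2 * k) * math.pi / k
    radii = np.where(np.arange(2 * k) % 2 == 0, outer_r, inner_r)
    return np.column_stack([center[0] + radii * np.sin(angles),
                            center[1] + radii * np.cos(angles)])


def star_perimeter(outer_r: float, inner_r: float, k: int) -> float:
    """Closed-form perimeter of the alternating-radius star polygon."""
    edge = math.sqrt(outer_r ** 2 + inner_r ** 2
                     - 2 * outer_r * inner_r * math.cos(math.pi / k))
    return 2 * k * edge


def star_circularity(outer_r: float, inner_r: float, k: int) -> float:
    """Analytic circularity of the star: enclosing circle radius is the
    outer radius, perimeter from the closed form."""
    p = star_perimeter(outer_r, inner_r, k)
    return 4.0 * math.pi * (math.pi * outer_r ** 2) / p ** 2


def star_inner_radius_for_circularity(outer_r: float, k: int,
                                      target: float) -> float:
    """Invert the analytic circularity for the inner radius.

    Solves ``star_circularity(R, r, k) == target`` for ``r``; raises
    :class:`SpecError` when the target is unreachable for this spike
    count.
    """
    s = math.pi * outer_r / (k * math.sqrt(target))
    t = math.cos(math.pi / k)
    disc = outer_r ** 2 * t ** 2 - outer_r ** 2 + s ** 2
    if disc < 0:
        raise SpecError(f"target circularity {target} unreachable with "
                        f"{k} spikes")
    r = outer_r * t - math.sqrt(disc)
    if not 0 < r < outer_r:
        raise SpecError(f"target circularity {target} unreachable with "
                        f"{k} spikes")
    return r


def generate_smear(spec: SmearSpec
                   ) -> tuple[list[SmearImage], pd.DataFrame]:
    """Generate smear fields plus a per-cell truth table.

    Cells are laid out on a jittered grid so nuclei never overlap; NET
    cells are star polygons with the spec's analytic target circularity,
    round cells are disks.  Marker channels are painted over the nucleus
    footprint of double-positive cells.
    """
    if not 0 <= spec.net_fraction <= 1:
        raise SpecError("net_fraction must be in [0, 1]")
    if not 0 <= spec.double_positive_fraction <= 1:
        raise SpecError("double_positive_fraction must be in [0, 1]")
    rng = np.random.default_rng(spec.seed)
    px = spec.pixel_size
    r_round_px = spec.nucleus_radius_um / px
    r_net_outer_px = spec.nucleus_radius_um / px  # same enclosing circle
    inner_px = star_inner_radius_for_circularity(
        r_net_outer_px, spec.star_points, spec.target_net_circularity)
    h, w = spec.field_shape
    spacing = int(4 * r_round_px)
    cols_n = max(1, (w - spacing) // spacing)
    rows_n = max(1, (h - spacing) // spacing)
    if rows_n * cols_n < spec.cells_per_field:
        raise SpecError("cells_per_field exceeds the non-overlap packing "
                        "limit for this field size")
    fields: list[SmearImage] = []
    truth_rows = []
    for f in range(spec.n_fields):
        dapi = np.abs(rng.normal(0, spec.background_sd, (h, w)))
        cd11b = np.abs(rng.normal(0, spec.background_sd, (h, w)))
        despr = np.abs(rng.normal(0, spec.background_sd, (h, w)))
        slots = [(spacing // 2 + spacing * i + spacing // 2,
                  spacing // 2 + spacing * j + spacing // 2)
                 for i in range(rows_n) for j in range(cols_n)]
        order = rng.permutation(len(slots))[:spec.cells_per_field]
        for cell_i, slot in enumerate(order):
            cy, cx = slots[slot]
            jit = rng.uniform(-0.1 * spacing, 0.1 * spacing, 2)
            cy, cx = float(cy + jit[0]), float(cx + jit[1])
            is_net = rng.uniform() < spec.net_fraction
            is_dp = rng.uniform() < spec.double_positive_fraction
            if is_net:
                verts = star_polygon((cy, cx), r_net_outer_px, inner_px,
                                     spec.star_points,
                                     phase=rng.uniform(0, 2 * math.pi))
                rr, cc = draw_polygon(verts[:, 0], verts[:, 1], (h, w))
                analytic_circ = star_circularity(
                    r_net_outer_px, inner_px, spec.star_points)
            else:
                rr, cc = draw_disk((cy, cx), r_round_px, shape=(h, w))
                analytic_circ = 1.0
            dapi[rr, cc] = rng.normal(spec.dapi_mean, spec.background_sd,
                                      rr.size)
            if is_dp:
                cd11b[rr, cc] = rng.normal(spec.marker_mean,
                                           spec.background_sd, rr.size)
                despr[rr, cc] = rng.normal(spec.marker_mean,
                                           spec.background_sd, rr.size)
            truth_rows.append({
                "field": f, "cell": cell_i, "center_row": cy,
                "center_col": cx, "is_net": is_net,
                "double_positive": is_dp,
                "analytic_circularity": analytic_circ,
            })
        fields.append(SmearImage(
            channels={"dapi": dapi, "cd11b": cd11b, "despr": despr},
            pixel_size=px, field_id=f"field{f:03d}"))
    return fields, pd.DataFrame(truth_rows)


# ------------------------------------------------------------ flow events


@dataclass
class FlowSpec:
    """Mixture of scatter clouds with a planted Q2 fraction.

    Scatter locations/scales are in arbitrary units matching the default
    neutrophil gate; fluorescence is lognormal background with a shifted
    positive population.
    """

    n_events: int = 50000
    neutrophil_frac: float = 0.6
    monocyte_frac: float = 0.2      # remainder: lymphocytes
    neutrophil_loc: tuple[float, float] = (700.0, 650.0)
    monocyte_loc: tuple[float, float] = (500.0, 150.0)
    lymphocyte_loc: tuple[float, float] = (250.0, 100.0)
    scatter_sd: float = 50.0
    q2_fraction: float = 0.10
    background_mu: float = 3.0      # log a.u.
    background_sigma: float = 0.5
    positive_shift: float = 3.5     # log-space shift of positive events
    n_isotype: int = 20000
    seed: int = 0


def generate_flow_events(spec: FlowSpec) -> pd.DataFrame:
    """Draw a stained-sample event table plus isotype-control events.

    Truth columns ``population`` and ``truth_q2`` ride along for scoring;
    consumers of the public schema ignore them.
    """
    if not 0 <= spec.q2_fraction <= 1:
        raise SpecError("q2_fraction must be in [0, 1]")
    if spec.neutrophil_frac + spec.monocyte_frac > 1:
        raise SpecError("population fractions exceed 1")
    rng = np.random.default_rng(spec.seed)
    n = spec.n_events
    u = rng.uniform(size=n)
    pop = np.where(u < spec.neutrophil_frac, "neutrophil",
                   np.where(u < spec.neutrophil_frac + spec.monocyte_frac,
                            "monocyte", "lymphocyte"))
    locs = {"neutrophil": spec.neutrophil_loc,
            "monocyte": spec.monocyte_loc,
            "lymphocyte": spec.lymphocyte_loc}
    fsc = np.empty(n)
    ssc = np.empty(n)
    for name, (lf, ls) in locs.items():
        sel = pop == name
        fsc[sel] = rng.normal(lf, spec.scatter_sd, sel.sum())
        ssc[sel] = rng.normal(ls, spec.scatter_sd, sel.sum())
    # fluorescence: lognormal background everywhere, planted double
    # positives among neutrophils only
    fl_despr = rng.lognormal(spec.background_mu, spec.background_sigma, n)
    fl_cd11b = rng.lognormal(spec.background_mu, spec.background_sigma, n)
    is_neut = pop == "neutrophil"
    dp = is_neut & (rng.uniform(size=n) < spec.q2_fraction)
    shift = math.exp(spec.positive_shift)
    fl_despr[dp] *= shift
    fl_cd11b[dp] *= shift
    sample = pd.DataFrame({
        "fsc": fsc, "ssc": ssc, "fl_despr": fl_despr, "fl_cd11b": fl_cd11b,
        "is_control": "stain", "population": pop, "truth_q2": dp,
    })
    iso = pd.DataFrame({
        "fsc": rng.normal(spec.neutrophil_loc[0], spec.scatter_sd,
                          spec.n_isotype),
        "ssc": rng.normal(spec.neutrophil_loc[1], spec.scatter_sd,
                          spec.n_isotype),
        "fl_despr": rng.lognormal(spec.background_mu, spec.background_sigma,
                                  spec.n_isotype),
        "fl_cd11b": rng.lognormal(spec.background_mu, spec.background_sigma,
                                  spec.n_isotype),
        "is_control": "isotype", "population": "neutrophil",
        "truth_q2": False,
    })
    return pd.concat([sample, iso], ignore_index=True)


def isotype_quantile(spec: FlowSpec, q: float) -> float:
    """Closed-form quantile of the isotype fluorescence distribution
    (lognormal with the spec's parameters)."""
    from scipy.stats import norm
    return math.exp(spec.background_mu
                    + spec.background_sigma * norm.ppf(q))


# ---------------------------------------------------------------- cohorts


@dataclass
class CohortSpec:
    """Gaussian-copula cohort with a target Spearman structure.

    ``target_spearman`` is on the Spearman scale; it is converted to the
    latent Pearson scale with the exact relation
    ``rho_P = 2 sin(pi * rho_S / 6)`` before the copula draw.  Marginals
    map column names to scipy frozen distributions (their ``ppf`` is
    applied to the copula uniforms); ``round_columns`` are rounded to
    integers afterwards (note this introduces ties).
    """

    n: int = 200
    columns: tuple[str, ...] = ("iph_vol", "phe_vol")
    target_spearman: np.ndarray | None = None
    marginals: dict | None = None
    round_columns: tuple[str, ...] = ()
    seed: int = 0


#: Marginal families loosely matched to the pilot cohort's ranges.
def default_marginals() -> dict:
    from scipy import stats as sps
    return {
        "iph_vol": sps.lognorm(s=1.2, scale=5.0),
        "phe_vol": sps.lognorm(s=1.1, scale=8.0),
        "nlr": sps.lognorm(s=0.8, scale=4.0),
        "rogue_n_count": sps.lognorm(s=0.9, scale=2000.0),
        "net_n_count": sps.lognorm(s=1.0, scale=700.0),
        "gcs": sps.uniform(loc=3, scale=12),
        "ich_score": sps.uniform(loc=0, scale=4.5),
        "mrs_90d": sps.uniform(loc=0, scale=6.5),
        "mgs": sps.uniform(loc=0, scale=21),
    }


def spearman_to_pearson_latent(rho_s: np.ndarray) -> np.ndarray:
    """Exact sine relation between Spearman targets and the latent
    Gaussian Pearson correlation."""
    return 2.0 * np.sin(np.pi * np.asarray(rho_s, dtype=float) / 6.0)


def generate_cohort(spec: CohortSpec) -> CohortTable:
    """Draw a synthetic cohort whose empirical Spearman matrix converges
    to the target as n grows."""
    cols = list(spec.columns)
    k = len(cols)
    target = (np.eye(k) if spec.target_spearman is None
              else np.asarray(spec.target_spearman, dtype=float))
    if target.shape != (k, k):
        raise SpecError("target matrix shape does not match columns")
    if not np.allclose(target, target.T) or not np.allclose(
            np.diag(target), 1.0):
        raise SpecError("target must be symmetric with unit diagonal")
    latent = spearman_to_pearson_latent(target)
    np.fill_diagonal(latent, 1.0)
    eigvals = np.linalg.eigvalsh(latent)
    if eigvals.min() < -1e-10:
        raise SpecError("target correlation matrix is not positive "
                        "semidefinite on the latent scale")
    rng = np.random.default_rng(spec.seed)
    # eigen square root tolerates semidefinite targets
    w, v = np.linalg.eigh(latent)
    root = v @ np.diag(np.sqrt(np.clip(w, 0, None))) @ v.T
    z = rng.standard_normal((spec.n, k)) @ root.T
    from scipy.stats import norm
    u = norm.cdf(z)
    marg = dict(default_marginals())
    if spec.marginals:
        marg.update(spec.marginals)
    data = {}
    for j, c in enumerate(cols):
        if c not in marg:
            raise SpecError(f"no marginal distribution for column {c!r}")
        x = marg[c].ppf(u[:, j])
        if c in spec.round_columns:
            x = np.round(x)
        data[c] = x
    df = pd.DataFrame(data)
    df.insert(0, "id", [str(i + 1) for i in range(spec.n)])
    return CohortTable(df)
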