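"""Synthetic H-DAB slide pairs and synthetic melanoma cohorts.

Two generators make every pipeline stage testable without any slide or
patient data:

* :func:`generate_ihc_pair` renders a stained/control image pair with
  per-cell ground truth.  A confluent tissue region (faintly
  counterstained cytoplasm with diffuse nonspecific brown background)
  sits on white glass; non-overlapping disc nuclei are drawn in
  hematoxylin, a chosen fraction of cells gets an annular DAB rim
  (membranous PD-L1), and brown melanin granules are replicated at
  identical positions on BOTH slides -- an idealized pair of consecutive
  sections.  RGB is formed by the forward Beer-Lambert model with the
  same H-DAB vectors the pipeline inverts, then i.i.d. Gaussian scanner
  noise is added per slide.

* :func:`generate_cohort` draws patient records whose physician/digital
  call margins and agreement, response rates, survival medians and
  covariate mix follow configurable study-level parameters.

All randomness flows from the single ``seed`` of the parameter object;
no global state is touched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .quantify import ROIPolygon, SlidePair
from .stains import RGBImage, hdab_stain_matrix
from .stats import PatientRecord

__all__ = [
    "ImageSimParams",
    "GroundTruth",
    "CohortSimParams",
    "generate_ihc_pair",
    "generate_cohort",
]


@dataclass
class ImageSimParams:
    """Parameters of the synthetic slide-pair renderer.

    Intensities are optical densities (OD).  ``pdl1_fraction`` of the
    cells receive a DAB rim; ``melanin_area_fraction`` is the fraction
    of the *tissue* area covered by pigment granules.  ``noise_sd`` is
    the per-channel Gaussian scanner noise in 8-bit intensity units.
    """

    width: int = 512
    height: int = 512
    n_cells: int = 150
    pdl1_fraction: float = 0.0
    melanin_area_fraction: float = 0.0
    nucleus_radius_px: int = 4
    rim_width_px: int = 3
    stain_intensity: float = 1.0  # DAB OD at the rim
    hematoxylin_od: float = 0.8  # nuclear OD
    melanin_od: float = 1.5  # granule OD
    cytoplasm_hematoxylin_od: float = 0.08
    cytoplasm_hematoxylin_sd: float = 0.04
    background_brown_sd: float = 0.05  # diffuse nonspecific chromogen
    noise_sd: float = 2.0
    melanin_jitter_px: int = 0  # displace control melanin to stress registration
    roi_margin_px: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.pdl1_fraction <= 1.0:
            raise ValueError("pdl1_fraction must lie in [0, 1]")
        if not 0.0 <= self.melanin_area_fraction <= 1.0:
            raise ValueError("melanin_area_fraction must lie in [0, 1]")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")


@dataclass
class GroundTruth:
    """Per-cell truth of a rendered pair."""

    centers: np.ndarray  # (n, 2) as (x, y)
    radii: np.ndarray
    labels: np.ndarray  # 'pdl1_pos' / 'negative' per cell
    melanin_mask: np.ndarray  # bool, stained-slide positions

    @property
    def n_cells(self) -> int:
        return len(self.radii)

    @property
    def true_fraction(self) -> float:
        if self.n_cells == 0:
            return 0.0
        return float(np.mean(self.labels == "pdl1_pos"))


def _disc_indices(cx: float, cy: float, radius: float, shape: tuple[int, int]):
    h, w = shape
    x0, x1 = max(0, int(cx - radius) - 1), min(w, int(cx + radius) + 2)
    y0, y1 = max(0, int(cy - radius) - 1), min(h, int(cy + radius) + 2)
    ys, xs = np.mgrid[y0:y1, x0:x1]
    inside = (xs - cx) ** 2 + (ys - cy) ** 2 <= radius**2
    return ys[inside], xs[inside]


def _place_cells(
    rng: np.random.Generator,
    p: ImageSimParams,
    center: tuple[float, float],
    axes: tuple[float, float],
) -> np.ndarray:
    """Rejection-sample non-overlapping cell centers inside the tissue.

    Cells keep a clearance of twice the outer (nucleus + rim) radius
    plus 2 px so that footprints, even dilated, never touch a
    neighbour's rim -- connected-component counting then recovers the
    exact cell count.
    """
    outer = p.nucleus_radius_px + p.rim_width_px
    min_sep = 2 * outer + 2
    margin = outer + p.roi_margin_px + 2
    cx, cy = center
    ax, ay = axes[0] - margin, axes[1] - margin
    if p.n_cells == 0:
        return np.empty((0, 2))
    if ax <= 0 or ay <= 0:
        raise ValueError("infeasible packing: tissue region smaller than one cell")
    placed: list[tuple[float, float]] = []
    grid: dict[tuple[int, int], list[int]] = {}
    cell_sz = min_sep
    max_tries = 200 * p.n_cells + 10000
    tries = 0
    while len(placed) < p.n_cells:
        tries += 1
        if tries > max_tries:
            raise ValueError(
                f"infeasible packing: placed {len(placed)} of {p.n_cells} cells "
                f"after {max_tries} attempts"
            )
        u, v = rng.uniform(-1.0, 1.0, 2)
        if u * u + v * v > 1.0:
            continue
        x, y = cx + u * ax, cy + v * ay
        gx, gy = int(x // cell_sz), int(y // cell_sz)
        ok = True
        for ddx in (-1, 0, 1):
            for ddy in (-1, 0, 1):
                for j in grid.get((gx + ddx, gy + ddy), ()):
                    px, py = placed[j]
                    if (px - x) ** 2 + (py - y) ** 2 < min_sep**2:
                        ok = False
                        break
                if not ok:
                    break
            if not ok:
                break
        if ok:
            grid.setdefault((gx, gy), []).append(len(placed))
            placed.append((x, y))
    return np.array(placed)


def generate_ihc_pair(p: ImageSimParams) -> tuple[SlidePair, GroundTruth]:
    """Render a stained/control slide pair with known per-cell truth.

    Deterministic given ``p.seed``; raises if the requested cells cannot
    be packed without overlap.
    """
    ss = np.random.SeedSequence(p.seed)
    rng_cells, rng_labels, rng_mel, rng_tex, rng_noise_s, rng_noise_c = (
        np.random.default_rng(s) for s in ss.spawn(6)
    )
    h, w = p.height, p.width
    shape = (h, w)
    center = (w / 2.0, h / 2.0)
    axes = (0.42 * w, 0.42 * h)

    # Tissue support: a centered ellipse of faintly stained tissue.
    ys, xs = np.mgrid[0:h, 0:w]
    tissue = ((xs - center[0]) / axes[0]) ** 2 + ((ys - center[1]) / axes[1]) ** 2 <= 1.0

    hem = np.zeros(shape)
    dab = np.zeros(shape)
    mel = np.zeros(shape)

    # Fine-grained tissue texture, identical on both slides (it is the
    # tissue itself, not scanner noise): light cytoplasmic counterstain
    # and diffuse nonspecific brown background.
    n_tissue = int(tissue.sum())
    hem[tissue] = p.cytoplasm_hematoxylin_od + np.abs(
        rng_tex.normal(0.0, p.cytoplasm_hematoxylin_sd, n_tissue)
    )
    brown_bg = np.zeros(shape)
    brown_bg[tissue] = np.abs(rng_tex.normal(0.0, p.background_brown_sd, n_tissue))

    centers = _place_cells(rng_cells, p, center, axes)
    n = len(centers)
    radii = np.full(n, float(p.nucleus_radius_px))
    labels = np.full(n, "negative", dtype=object)
    n_pos = int(round(p.pdl1_fraction * n))
    if n_pos > 0:
        pos_idx = rng_labels.permutation(n)[:n_pos]
        labels[pos_idx] = "pdl1_pos"

    outer = p.nucleus_radius_px + p.rim_width_px
    for i, (cx, cy) in enumerate(centers):
        yy, xx = _disc_indices(cx, cy, p.nucleus_radius_px, shape)
        hem[yy, xx] = p.hematoxylin_od * rng_labels.uniform(0.9, 1.1)
        if labels[i] == "pdl1_pos":
            yo, xo = _disc_indices(cx, cy, outer, shape)
            ring = (xo - cx) ** 2 + (yo - cy) ** 2 > p.nucleus_radius_px**2
            dab[yo[ring], xo[ring]] = p.stain_intensity * rng_labels.uniform(0.85, 1.15)

    # Melanin granules: small discs of variable pigment density, drawn
    # until the requested fraction of the tissue area is covered.
    melanin_mask = np.zeros(shape, dtype=bool)
    target = p.melanin_area_fraction * n_tissue
    guard = 0
    while melanin_mask.sum() < target:
        guard += 1
        if guard > 10 * n_tissue:
            raise ValueError("melanin coverage target unreachable")
        gx = rng_mel.uniform(center[0] - axes[0], center[0] + axes[0])
        gy = rng_mel.uniform(center[1] - axes[1], center[1] + axes[1])
        if ((gx - center[0]) / axes[0]) ** 2 + ((gy - center[1]) / axes[1]) ** 2 > 0.9:
            continue
        r = rng_mel.uniform(2.0, 4.0)
        od = p.melanin_od * rng_mel.uniform(0.85, 1.15)
        yy, xx = _disc_indices(gx, gy, r, shape)
        mel[yy, xx] = np.maximum(mel[yy, xx], od)
        melanin_mask[yy, xx] = True

    if p.melanin_jitter_px:
        jx, jy = rng_mel.integers(-p.melanin_jitter_px, p.melanin_jitter_px + 1, 2)
        mel_c = np.roll(np.roll(mel, int(jy), axis=0), int(jx), axis=1)
    else:
        mel_c = mel

    matrix = hdab_stain_matrix()
    hvec, dvec = matrix[0], matrix[1]

    def render(hem_map, brown_map, rng_noise):
        od = hem_map[..., None] * hvec + brown_map[..., None] * dvec
        rgb = 255.0 * 10.0 ** (-od)
        rgb = rgb + rng_noise.normal(0.0, p.noise_sd, rgb.shape)
        return RGBImage(np.clip(np.round(rgb), 0, 255).astype(np.uint8))

    stained = render(hem, dab + mel + brown_bg, rng_noise_s)
    control = render(hem, mel_c + brown_bg, rng_noise_c)

    m = p.roi_margin_px
    roi = ROIPolygon([(m, m), (w - 1 - m, m), (w - 1 - m, h - 1 - m), (m, h - 1 - m)])
    pair = SlidePair(
        stained=stained,
        control=control,
        roi_stained=roi,
        roi_control=ROIPolygon(list(roi.vertices)),
    )
    truth = GroundTruth(
        centers=centers, radii=radii, labels=labels, melanin_mask=melanin_mask
    )
    return pair, truth


# ---------------------------------------------------------------------------
# Cohort generator
# ---------------------------------------------------------------------------

#: Baseline covariate prevalences of a metastatic melanoma ICB cohort
#: (fraction of patients with the risk-factor level of each binary).
DEFAULT_COVARIATE_MIX: dict[str, float] = {
    "age_gt65": 0.45,
    "sex_male": 99 / 156,
    "stage_iv": 135 / 156,
    "primary_skin": 140 / 156,
    "m_cat_high": 68 / 156,
    "ldh_elevated": 50 / 156,
    "combo_therapy": 41 / 156,
    "braf_mutant": 60 / 153,
}

#: Covariates with a small missingness rate, mimicking registry data.
DEFAULT_MISSING_RATES: dict[str, float] = {"ldh_elevated": 2 / 156, "braf_mutant": 3 / 156}


@dataclass
class CohortSimParams:
    """Study-level parameters of the synthetic cohort.

    The binary physician/digital calls are drawn from the joint 2x2
    distribution implied by the two marginal positivity probabilities
    and the overall agreement probability.  Best overall response is
    Bernoulli with a rate per joint call cell; survival times are
    exponential with a median per digital call (``None`` disables an
    endpoint's event entirely); censoring is uniform on
    ``(0, 2 * followup_median)`` so the median follow-up matches
    ``followup_median``.
    """

    n_patients: int = 156
    p_pos_physician: float = 60 / 156
    p_pos_digital: float = 95 / 156
    p_agree: float = 99 / 156
    bor_rate_both_pos: float = 0.604
    bor_rate_digital_only: float = 0.400
    bor_rate_physician_only: float = 0.272
    bor_rate_both_neg: float = 0.334
    pfs_median_pos: float = 9.9
    pfs_median_neg: float = 4.6
    os_median_pos: float = 40.0  # 'not reached' at the study's follow-up
    os_median_neg: float = 13.0
    followup_median: float = 26.4
    covariate_mix: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_MIX)
    )
    missing_rates: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MISSING_RATES)
    )
    seed: int = 0

    def joint_call_probs(self) -> dict[str, float]:
        """The 2x2 joint call distribution; raises on infeasible margins.

        Solves ``p11`` from ``agreement = p11 + p00`` and the margins;
        the result must respect the Frechet bounds
        ``max(0, p_phys + p_dig - 1) <= p11 <= min(p_phys, p_dig)``.
        """
        pp, pd, pa = self.p_pos_physician, self.p_pos_digital, self.p_agree
        for name, v in (("p_pos_physician", pp), ("p_pos_digital", pd), ("p_agree", pa)):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        p11 = (pa + pp + pd - 1.0) / 2.0
        lo, hi = max(0.0, pp + pd - 1.0), min(pp, pd)
        eps = 1e-9
        if p11 < lo - eps:
            raise ValueError(
                f"inconsistent margins: implied p(both positive)={p11:.4f} violates the "
                f"lower Frechet bound max(0, p_phys + p_dig - 1) = {lo:.4f}"
            )
        if p11 > hi + eps:
            raise ValueError(
                f"inconsistent margins: implied p(both positive)={p11:.4f} violates the "
                f"upper Frechet bound min(p_phys, p_dig) = {hi:.4f}"
            )
        p11 = min(max(p11, lo), hi)
        probs = {
            "both_positive": p11,
            "digital_only": pd - p11,
            "physician_only": pp - p11,
            "both_negative": 1.0 - pd - pp + p11,
        }
        for k, v in probs.items():
            if v < -eps:
                raise ValueError(f"inconsistent margins: p({k}) = {v:.4f} < 0")
            probs[k] = max(v, 0.0)
        return probs


_LN2 = math.log(2.0)


def generate_cohort(p: CohortSimParams) -> list[PatientRecord]:
    """Draw a synthetic cohort of patient records; deterministic per seed."""
    probs = p.joint_call_probs()
    rng = np.random.default_rng(np.random.SeedSequence(p.seed))
    cells = list(probs)
    cum = np.cumsum([probs[c] for c in cells])
    bor_rate = {
        "both_positive": p.bor_rate_both_pos,
        "digital_only": p.bor_rate_digital_only,
        "physician_only": p.bor_rate_physician_only,
        "both_negative": p.bor_rate_both_neg,
    }
    records: list[PatientRecord] = []
    for i in range(p.n_patients):
        u = rng.random()
        cell = cells[int(np.searchsorted(cum, u, side="right"))] if u < cum[-1] else cells[-1]
        phys = "positive" if cell in ("both_positive", "physician_only") else "negative"
        dig = "positive" if cell in ("both_positive", "digital_only") else "negative"
        # Percentages share one latent severity so the two raters correlate.
        sev = rng.random()
        dig_pct = 5.0 + 75.0 * sev if dig == "positive" else 5.0 * sev
        phys_pct = 5.0 + 75.0 * sev if phys == "positive" else 5.0 * sev
        responder = bool(rng.random() < bor_rate[cell])
        pfs_med = p.pfs_median_pos if dig == "positive" else p.pfs_median_neg
        os_med = p.os_median_pos if dig == "positive" else p.os_median_neg
        t_pfs = rng.exponential(pfs_med / _LN2)
        t_os = rng.exponential(os_med / _LN2)
        censor = rng.uniform(0.0, 2.0 * p.followup_median)
        covs: dict[str, bool | None] = {}
        for name, prev in p.covariate_mix.items():
            val: bool | None = bool(rng.random() < prev)
            if rng.random() < p.missing_rates.get(name, 0.0):
                val = None
            covs[name] = val
        records.append(
            PatientRecord(
                id=f"P{i + 1:04d}",
                physician_call=phys,
                digital_call=dig,
                physician_pct=round(phys_pct, 1),
                digital_pct=round(dig_pct, 1),
                bor_responder=responder,
                pfs_months=round(min(t_pfs, censor), 2),
                os_months=round(min(t_os, censor), 2),
                pfs_event=bool(t_pfs <= censor),
                os_event=bool(t_os <= censor),
                **covs,
            )
        )
    return records
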