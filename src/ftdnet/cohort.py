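"""Seeded synthetic cohorts emulating a genetic-FTD family study.

No imaging data are distributed with multicentre genetic-FTD cohorts, so
every downstream stage of this package is exercised on synthetic cohorts
whose *statistical* structure mirrors the study design: three groups
(gene-negative relatives, presymptomatic carriers, symptomatic FTD) of
configurable size (default 80/68/24), multi-site acquisition with TR around
2.2 s, per-family expected-onset ages (years-to-onset negative before
expected onset), per-subject motion spike percentages, brain volume as a
percentage of total intracranial volume, and cognitive z-scores.

The generative model for connectivity is a hub-structured ring-of-communities
covariance:

* regions form communities arranged on a ring, with high within-community
  and moderate ring-adjacent correlation — a segregated, lattice-like
  baseline that is near-positive-semi-definite by construction;
* a fixed, evenly spaced hub set carries elevated local correlations, so
  realized hub connection strengths stand >2 SD above the regional mean;
* the subject's organization level (lambda) sets how many long-range pairs
  carry a strong correlation — small-world shortcuts that control how
  topologically efficient the realized network is relative to
  degree-preserving nulls.  Lambda rises toward expected onset (the
  resilience/compensation phase, ``carrier_efficiency_offset``) and
  declines after it (``post_onset_efficiency_slope``);
* connectivity loss is pruning: the fraction of local connections retained
  declines linearly along the family onset axis (plus an optional
  symptomatic multiplier ``ftd_strength_scale``), lowering connection
  strength without touching the amplitude, and hence the estimation-noise
  behaviour, of surviving connections.

Connection strength therefore falls smoothly along the onset axis — FTD
subjects sit furthest along the gradient — while network efficiency holds
up until expected onset and breaks down after it.

BOLD-like signals are multivariate Gaussian innovations with the target
covariance, bandpass-filtered into the analysis band; wavelet-scale
correlations of such signals converge to the target correlations.

The module also provides cheap outcome-level simulators (drawing network
metrics directly from the same effect structure, without time series) for
power and calibration studies, and a centroidal-Voronoi-tessellation
parcellation generator (Lloyd's algorithm on voxel coordinates).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sp_signal
from scipy.spatial import cKDTree

from .connectivity import ParcellatedTimeSeries, select_wavelet_scale

__all__ = [
    "CohortConfig",
    "SubjectRecord",
    "GroundTruthRecord",
    "generate_cohort",
    "CovarianceTemplate",
    "covariance_template",
    "subject_covariance",
    "simulate_bold",
    "generate_cvt_parcellation",
    "cvt_energy",
    "simulate_group_outcome_table",
    "simulate_breakpoint_table",
    "simulate_regional_strength_table",
]

GENE_LABELS = ("C9orf72", "MAPT", "GRN")
COGNITIVE_TESTS = ("mmse", "trails_a", "trails_b", "digit_span_forward", "verbal_fluency_letter")

# group-level demographics: mean age (and SD) per group, male fraction
_AGE_BY_GROUP = {"gene_negative": (47.8, 15.5), "carrier": (44.5, 12.3), "ftd": (62.4, 8.6)}
_MALE_FRAC = {"gene_negative": 0.61, "carrier": 0.59, "ftd": 0.29}
_GENE_PROBS = {
    "gene_negative": (0.25, 0.19, 0.56),
    "carrier": (0.25, 0.19, 0.56),
    "ftd": (0.41, 0.38, 0.21),
}


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for a synthetic cohort.

    The defaults are the analyzed-cohort conditions: group sizes 80/68/24,
    ~500-region parcellations scaled down to 90 regions for desk-scale runs,
    TR 2.2 s over >=300 s of acquisition, five scan sites, and disease
    effects sized so that the group, trajectory, and coupling effects are of
    the same order as those reported for the real cohort.
    """

    n_gene_negative: int = 80
    n_carrier: int = 68
    n_ftd: int = 24
    n_regions: int = 90
    n_timepoints: int = 512
    tr_seconds: float = 2.2
    n_sites: int = 5
    gene_labels: tuple = GENE_LABELS
    seed: int = 0
    # connectivity structure
    hub_fraction: float = 0.10
    hub_within_corr: float = 0.65  # hub rows' within-community correlation (drives 2-SD strengths)
    hub_adjacent_corr: float = 0.30  # hub rows' correlation into the two neighbouring communities
    within_community_corr: float = 0.45  # correlation inside a community
    adjacent_community_corr: float = 0.18  # correlation between ring-adjacent communities
    long_range_corr: float = 0.35  # correlation carried by active long-range (integration) pairs
    between_community_corr: float = 0.0  # background correlation at ring distance >= 2
    community_size: int = 6
    n_long_range_base: int = 20  # long-range pairs active at organization level lambda = 1
    # disease effects
    ftd_strength_scale: float = 1.0  # symptomatic multiplier on off-diagonal covariance
    strength_decline_per_year: float = 0.008  # connectivity loss per year along the onset axis
    strength_decline_onset_years: float = -25.0  # where the loss gradient starts, relative to onset
    carrier_efficiency_offset: float = 0.25  # organization gain reached at expected onset
    post_onset_efficiency_slope: float = -0.12  # organization decline per year after onset
    # outcome couplings
    volume_coupling_r: float = 0.65  # target strength-volume correlation in FTD
    cognition_coupling: dict = field(
        default_factory=lambda: {"mmse": 0.45, "trails_a": 0.45}
    )
    # noise
    noise_sd: float = 0.05  # lognormal SD of per-subject strength/organization jitter
    covariance_jitter_sd: float = 0.01  # entrywise covariance jitter before PSD projection
    spike_pct_distribution: dict = field(
        default_factory=lambda: {"alpha": 2.0, "beta": 9.0, "scale": 8.0, "frac_high": 0.0}
    )

    def __post_init__(self) -> None:
        for name in ("n_gene_negative", "n_carrier", "n_ftd", "n_regions", "n_timepoints"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_regions < 2 or self.n_timepoints < 8:
            raise ValueError("need at least 2 regions and 8 timepoints")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if not (0 <= self.hub_fraction <= 1):
            raise ValueError("hub_fraction must lie in [0, 1]")
        if not (0 < self.ftd_strength_scale <= 1):
            raise ValueError("ftd_strength_scale must lie in (0, 1]")
        if not (0 <= self.between_community_corr < self.adjacent_community_corr
                < self.long_range_corr):
            raise ValueError(
                "require background < adjacent_community_corr < long_range_corr"
            )

    @property
    def n_total(self) -> int:
        return self.n_gene_negative + self.n_carrier + self.n_ftd


@dataclass
class SubjectRecord:
    subject_id: str
    group: str
    age: float
    sex: str
    site: str
    gene: str
    years_to_expected_onset: float
    spike_pct: float
    brain_volume_pct: float
    cognitive_scores: dict

    def __post_init__(self) -> None:
        if self.group not in ("gene_negative", "carrier", "ftd"):
            raise ValueError(f"invalid group {self.group!r}")
        if not (0 <= self.spike_pct <= 100):
            raise ValueError("spike_pct must lie in [0, 100]")
        if not (0 < self.brain_volume_pct < 100):
            raise ValueError("brain_volume_pct must lie in (0, 100)")


@dataclass
class GroundTruthRecord:
    """Generator internals echoed per subject, enabling parameter recovery tests."""

    subject_id: str
    true_covariance_summary: float  # mean off-diagonal correlation of the target covariance
    true_hub_set: tuple
    imposed_group_effect: dict
    imposed_breakpoint_slopes: dict


def _hub_set(config: CohortConfig) -> np.ndarray:
    n_hub = int(round(config.hub_fraction * config.n_regions))
    if n_hub == 0:
        return np.array([], dtype=int)
    return np.unique(np.linspace(0, config.n_regions - 1, n_hub).round().astype(int))


def _communities(config: CohortConfig) -> np.ndarray:
    return np.arange(config.n_regions) // max(2, config.community_size)


def _organization_level(config: CohortConfig, group: str, years_to_onset: float) -> float:
    """Integration-overlay amplitude lambda: rises toward onset, falls after."""
    if group == "gene_negative":
        return 1.0
    t = years_to_onset
    if t <= 0:
        return 1.0 + config.carrier_efficiency_offset * max(0.0, (t + 25.0)) / 25.0
    return 1.0 + config.carrier_efficiency_offset + config.post_onset_efficiency_slope * t


def _strength_scale(config: CohortConfig, group: str, years_to_onset: float) -> float:
    """Connection-retention fraction for one subject.

    The fraction of local structural connections retained declines linearly
    along the family onset axis for every family member (the gradient starts
    ``strength_decline_onset_years`` before expected onset, i.e. at the left
    edge of the cohort's onset range by default, so the loss is smooth in
    years-to-onset with no kink at onset); symptomatic subjects are
    additionally scaled by ``ftd_strength_scale``.  Group differences in
    connection strength then arise from where each group sits on the onset
    axis — FTD furthest along — rather than from a step at the diagnosis
    boundary.
    """
    ramp = max(0.0, years_to_onset - config.strength_decline_onset_years)
    s = max(0.1, 1.0 - config.strength_decline_per_year * ramp)
    if group == "ftd":
        s *= config.ftd_strength_scale
    return s


def _nearest_correlation(c: np.ndarray) -> np.ndarray:
    """Clip eigenvalues to make the matrix PSD, then renormalize the diagonal."""
    c = (c + c.T) / 2.0
    w, v = np.linalg.eigh(c)
    w = np.clip(w, 1e-6, None)
    c = (v * w) @ v.T
    d = np.sqrt(np.diag(c))
    c = c / np.outer(d, d)
    np.fill_diagonal(c, 1.0)
    return c


@dataclass(frozen=True)
class CovarianceTemplate:
    """Cohort-level structural layout shared by every subject.

    ``base`` holds the subject-independent correlation structure: communities
    arranged on a ring (within-community and ring-adjacent correlations, a
    factor-consistent layout that is close to positive semi-definite by
    construction) plus the hub overlay.  ``long_range_pairs`` is a seeded
    random ordering of candidate pairs at ring distance >= 2; a subject's
    active long-range set is the first k entries, so higher organization
    activates a superset of the pairs active at lower organization.
    """

    base: np.ndarray
    long_range_pairs: np.ndarray  # (n, 2) candidate pairs at ring distance >= 2
    local_pairs: np.ndarray  # (n, 2) non-hub within/adjacent pairs in pruning order
    hub_set: tuple


def covariance_template(config: CohortConfig) -> CovarianceTemplate:
    """Build the cohort's structural template (deterministic in config.seed).

    Communities of ``community_size`` regions sit on a ring: correlations are
    ``within_community_corr`` inside a community, ``adjacent_community_corr``
    between ring neighbours, and ``between_community_corr`` (default 0) at
    larger ring distances — a segregated, lattice-like baseline whose
    integration is controlled per subject by long-range pairs.  Hub regions
    carry elevated within- and adjacent-community correlations, which makes
    their connection strengths stand >2 SD above the across-region mean.
    """
    R = config.n_regions
    comm = _communities(config)
    n_comm = int(comm.max()) + 1
    rng = np.random.default_rng((config.seed * 2654435761 + 97) % 2**31)

    dc = np.abs(comm[:, None] - comm[None, :])
    ring = np.minimum(dc, n_comm - dc)
    base = np.full((R, R), config.between_community_corr, dtype=float)
    base[ring == 1] = config.adjacent_community_corr
    base[ring == 0] = config.within_community_corr

    hubs = _hub_set(config)
    hub_mask = np.zeros(R, dtype=bool)
    hub_mask[hubs] = True
    for h in hubs:
        mates = ring[h] == 0
        adj = ring[h] == 1
        base[h, mates] = base[mates, h] = config.hub_within_corr
        base[h, adj] = base[adj, h] = config.hub_adjacent_corr
    np.fill_diagonal(base, 1.0)

    iu, ju = np.triu_indices(R, 1)
    nonhub = ~hub_mask[iu] & ~hub_mask[ju]
    candidates = np.flatnonzero((ring[iu, ju] >= 2) & nonhub)
    candidates = candidates[rng.permutation(candidates.size)]
    local = np.flatnonzero((ring[iu, ju] <= 1) & nonhub)
    local = local[rng.permutation(local.size)]
    return CovarianceTemplate(
        base=base,
        long_range_pairs=np.column_stack([iu[candidates], ju[candidates]]),
        local_pairs=np.column_stack([iu[local], ju[local]]),
        hub_set=tuple(int(h) for h in hubs),
    )


def subject_covariance(
    config: CohortConfig,
    group: str,
    years_to_onset: float,
    strength_jitter: float = 1.0,
    organization_jitter: float = 1.0,
    rng: np.random.Generator | None = None,
    template: CovarianceTemplate | None = None,
) -> np.ndarray:
    """Target correlation matrix for one subject under the generative model.

    Two dials act on the template.  The integration level lambda sets how
    many long-range pairs (ring distance >= 2) carry ``long_range_corr`` —
    the network's small-world shortcuts, which make the realized graph
    topologically efficient relative to degree-preserving nulls.  The
    connection-retention fraction prunes non-hub local (within/adjacent
    community) pairs back to the background correlation: pruned connections
    lower total connection strength while leaving the correlation amplitude
    of surviving connections — and hence the topology-selection noise —
    unchanged.  Finally the matrix is jittered entrywise and projected to
    the nearest correlation matrix (mild, because the ring-block layout is
    near-PSD by construction).
    """
    if template is None:
        template = covariance_template(config)
    base = template.base.copy()

    lam = _organization_level(config, group, years_to_onset) * organization_jitter
    k = int(round(config.n_long_range_base * max(lam, 0.0)))
    k = min(k, len(template.long_range_pairs))
    if k:
        sel = template.long_range_pairs[:k]
        base[sel[:, 0], sel[:, 1]] = config.long_range_corr
        base[sel[:, 1], sel[:, 0]] = config.long_range_corr

    retain = float(np.clip(_strength_scale(config, group, years_to_onset) * strength_jitter,
                           0.1, 1.0))
    n_drop = int(round((1.0 - retain) * len(template.local_pairs)))
    if n_drop:
        drop = template.local_pairs[-n_drop:]
        base[drop[:, 0], drop[:, 1]] = config.between_community_corr
        base[drop[:, 1], drop[:, 0]] = config.between_community_corr
    c = base
    if rng is not None and config.covariance_jitter_sd > 0:
        j = rng.normal(0.0, config.covariance_jitter_sd, size=(c.shape[0], c.shape[0]))
        c = c + (j + j.T) / 2.0
    np.fill_diagonal(c, 1.0)
    return _nearest_correlation(np.clip(c, -0.99, 0.99))


def simulate_bold(
    covariance: np.ndarray,
    n_timepoints: int,
    tr_seconds: float,
    band: WaveletBand,
    seed: int,
) -> np.ndarray:
    """Band-limited Gaussian signals with a target cross-regional covariance.

    Draws multivariate Gaussian innovations with the given covariance and
    bandpass-filters them into the analysis band.  Filtering is applied
    identically to every region, so cross-regional correlations — including
    wavelet-scale correlations — converge to the target as T grows.
    """
    cov = np.asarray(covariance, dtype=float)
    if cov.ndim != 2 or cov.shape[0] != cov.shape[1]:
        raise ValueError("covariance must be square")
    if not np.allclose(cov, cov.T, atol=1e-10):
        raise ValueError("covariance must be symmetric")
    w = np.linalg.eigvalsh(cov)
    if w.min() < -1e-8 * max(1.0, w.max()):
        raise ValueError("covariance is not positive semi-definite")
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(cov + 1e-10 * np.eye(cov.shape[0]))
    x = L @ rng.standard_normal((cov.shape[0], n_timepoints))
    nyq = 0.5 / tr_seconds
    lo = max(band.f_low / nyq, 1e-3)
    hi = min(band.f_high / nyq, 1 - 1e-3)
    if lo >= hi:
        raise ValueError("analysis band infeasible for this tr_seconds")
    b, a = sp_signal.butter(3, [lo, hi], btype="band")
    return sp_signal.filtfilt(b, a, x, axis=-1)


def _spike_percentages(config: CohortConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    p = config.spike_pct_distribution
    low = rng.beta(p.get("alpha", 2.0), p.get("beta", 9.0), size=n) * p.get("scale", 8.0)
    n_high = int(round(p.get("frac_high", 0.0) * n))
    if n_high:
        idx = rng.choice(n, size=n_high, replace=False)
        low[idx] = 10.0 + rng.beta(2.0, 5.0, size=n_high) * 25.0
    return np.clip(low, 0.0, 100.0)


def generate_cohort(config: CohortConfig):
    """Generate one cohort: metadata, BOLD-like series, and ground truth.

    Returns ``(subjects, timeseries, ground_truth)`` — one entry of each per
    subject, fully reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    band = select_wavelet_scale(config.tr_seconds)  # raises if band infeasible

    groups = (
        ["gene_negative"] * config.n_gene_negative
        + ["carrier"] * config.n_carrier
        + ["ftd"] * config.n_ftd
    )
    n = len(groups)
    hubs = _hub_set(config)
    template = covariance_template(config)
    spike = _spike_percentages(config, n, rng)

    subjects, series, truth = [], [], []
    for i, group in enumerate(groups):
        sid = f"S{i + 1:03d}"
        mu, sd = _AGE_BY_GROUP[group]
        age = float(np.clip(rng.normal(mu, sd), 18.0, 85.0))
        sex = "M" if rng.random() < _MALE_FRAC[group] else "F"
        site = f"site{rng.integers(config.n_sites) + 1}"
        gene = str(rng.choice(config.gene_labels, p=_GENE_PROBS[group]))
        if group == "carrier":
            t_onset = float(rng.uniform(-25.0, -1.0))
        elif group == "ftd":
            t_onset = float(rng.uniform(0.0, 10.0))
        else:
            t_onset = float(rng.uniform(-25.0, 5.0))

        jitter_s = float(np.exp(rng.normal(0.0, config.noise_sd)))
        jitter_o = float(np.exp(rng.normal(0.0, config.noise_sd)))
        cov = subject_covariance(config, group, t_onset, jitter_s, jitter_o, rng,
                                 template=template)
        x = simulate_bold(
            cov, config.n_timepoints, config.tr_seconds, band,
            seed=int(rng.integers(2**31 - 1)),
        )
        series.append(ParcellatedTimeSeries(sid, x, config.tr_seconds))

        off = cov[~np.eye(config.n_regions, dtype=bool)]
        mean_off = float(off.mean())

        # brain volume: FTD volumes couple to the subject's connectivity level
        if group == "ftd":
            rho = config.volume_coupling_r
            z = (np.log(jitter_s)) / max(config.noise_sd, 1e-6)
            vol = 76.0 + 4.0 * (rho * z + np.sqrt(max(0.0, 1 - rho**2)) * rng.standard_normal())
        else:
            vol = rng.normal(82.0, 3.0)
        vol = float(np.clip(vol, 50.0, 95.0))

        # cognition: z-scores linear in the subject's connectivity/organization
        # levels, with a symptomatic intercept shift
        scores = {}
        z_s = np.log(jitter_s) / max(config.noise_sd, 1e-6)
        for test in COGNITIVE_TESTS:
            base = -2.0 if group == "ftd" else 0.0
            coef = config.cognition_coupling.get(test, 0.0)
            scores[test] = float(base + coef * z_s + rng.normal(0.0, 0.9))

        subjects.append(
            SubjectRecord(
                subject_id=sid,
                group=group,
                age=age,
                sex=sex,
                site=site,
                gene=gene,
                years_to_expected_onset=t_onset,
                spike_pct=float(spike[i]),
                brain_volume_pct=vol,
                cognitive_scores=scores,
            )
        )
        truth.append(
            GroundTruthRecord(
                subject_id=sid,
                true_covariance_summary=mean_off,
                true_hub_set=tuple(int(h) for h in hubs),
                imposed_group_effect={
                    "ftd_strength_scale": config.ftd_strength_scale,
                    "strength_scale": _strength_scale(config, group, t_onset),
                    "organization_level": _organization_level(config, group, t_onset),
                },
                imposed_breakpoint_slopes={
                    "strength_decline_per_year": config.strength_decline_per_year,
                    "post_onset_efficiency_slope": config.post_onset_efficiency_slope,
                },
            )
        )
    return subjects, series, truth


# ---------------------------------------------------------------------------
# centroidal Voronoi tessellation parcellation (Lloyd's algorithm)
# ---------------------------------------------------------------------------

def cvt_energy(voxels: np.ndarray, labels: np.ndarray, centroids: np.ndarray) -> float:
    """Quantization energy: sum of squared voxel-to-assigned-centroid distances."""
    return float(((voxels - centroids[labels - 1]) ** 2).sum())


def generate_cvt_parcellation(
    mask_voxels: np.ndarray,
    k: int,
    n_iterations: int = 50,
    seed: int = 0,
    return_history: bool = False,
):
    """Partition mask voxels into k approximately equally sized parcels.

    Lloyd's algorithm: alternate nearest-centroid assignment and centroid
    recomputation until convergence or ``n_iterations``; both steps are
    non-increasing in the quantization energy.  Empty parcels are reseeded at
    the voxel farthest from its centroid.  Returns integer labels 1..k per
    voxel (and, optionally, the per-iteration energy history).
    """
    voxels = np.asarray(mask_voxels, dtype=float)
    if voxels.ndim != 2:
        raise ValueError("mask_voxels must be an (n_voxels, n_dims) array")
    n = voxels.shape[0]
    if not (1 <= k <= n):
        raise ValueError(f"k={k} must lie in [1, n_voxels={n}]")
    rng = np.random.default_rng(seed)
    if k == 1:
        labels = np.ones(n, dtype=int)
        return (labels, [cvt_energy(voxels, labels, voxels.mean(0, keepdims=True))]) if return_history else labels

    centroids = voxels[rng.choice(n, size=k, replace=False)]
    labels = np.zeros(n, dtype=int)
    history = []
    for _ in range(n_iterations):
        new_labels = cKDTree(centroids).query(voxels)[1] + 1
        # reseed empty parcels at the worst-quantized voxel
        for parcel in range(1, k + 1):
            if not (new_labels == parcel).any():
                d2 = ((voxels - centroids[new_labels - 1]) ** 2).sum(1)
                far = int(np.argmax(d2))
                new_labels[far] = parcel
                centroids[parcel - 1] = voxels[far]
        if (new_labels == labels).all():
            break
        labels = new_labels
        for parcel in range(1, k + 1):
            centroids[parcel - 1] = voxels[labels == parcel].mean(axis=0)
        history.append(cvt_energy(voxels, labels, centroids))
    return (labels, history) if return_history else labels


# ---------------------------------------------------------------------------
# outcome-level simulators (network metrics drawn directly, no time series)
# ---------------------------------------------------------------------------

def _metadata_frame(n_by_group: dict, rng: np.random.Generator, n_sites: int = 5) -> pd.DataFrame:
    rows = []
    i = 0
    for group, n in n_by_group.items():
        mu, sd = _AGE_BY_GROUP[group]
        for _ in range(n):
            i += 1
            if group == "carrier":
                t = rng.uniform(-25.0, -1.0)
            elif group == "ftd":
                t = rng.uniform(0.0, 10.0)
            else:
                t = rng.uniform(-25.0, 5.0)
            rows.append(
                {
                    "subject_id": f"S{i:03d}",
                    "group": group,
                    "age": float(np.clip(rng.normal(mu, sd), 18, 85)),
                    "site": f"site{rng.integers(n_sites) + 1}",
                    "gene": str(rng.choice(GENE_LABELS, p=_GENE_PROBS[group])),
                    "years_to_expected_onset": float(t),
                }
            )
    return pd.DataFrame(rows)


def simulate_group_outcome_table(
    n_gene_negative: int = 80,
    n_carrier: int = 68,
    n_ftd: int = 24,
    *,
    baseline: float = 147.0,
    carrier_offset: float = 2.0,
    ftd_deficit: float = 27.0,
    age_slope: float = 0.0,
    noise_sd: float = 30.0,
    n_sites: int = 5,
    site_sd: float = 8.0,
    gene_sd: float = 5.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Subject-level outcomes with a known FTD deficit and crossed random effects.

    Carriers sit at ``baseline + carrier_offset`` and FTD at ``baseline +
    carrier_offset - ftd_deficit``, so the true carrier-minus-FTD contrast is
    exactly ``ftd_deficit``.  Used for bias and power studies of the
    group-contrast machinery.
    """
    rng = np.random.default_rng(seed)
    df = _metadata_frame(
        {"gene_negative": n_gene_negative, "carrier": n_carrier, "ftd": n_ftd}, rng, n_sites
    )
    u_site = {f"site{j + 1}": rng.normal(0, site_sd) for j in range(n_sites)}
    u_gene = {g: rng.normal(0, gene_sd) for g in GENE_LABELS}
    mean = baseline + np.where(df["group"] != "gene_negative", carrier_offset, 0.0)
    mean = mean - np.where(df["group"] == "ftd", ftd_deficit, 0.0)
    mean = mean + age_slope * (df["age"] - 50.0)
    df["outcome"] = (
        mean
        + df["site"].map(u_site).to_numpy()
        + df["gene"].map(u_gene).to_numpy()
        + rng.normal(0, noise_sd, len(df))
    )
    return df


def simulate_breakpoint_table(
    n_carrier: int = 68,
    n_ftd: int = 24,
    *,
    baseline: float = 1.0,
    pre_slope: float = 0.0,
    slope_change: float = 0.0,
    level_change: float = 0.0,
    knot: float = 0.0,
    noise_sd: float = 0.05,
    n_sites: int = 1,
    site_sd: float = 0.0,
    gene_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Carrier + FTD outcomes following a known piecewise-linear trajectory."""
    rng = np.random.default_rng(seed)
    df = _metadata_frame({"carrier": n_carrier, "ftd": n_ftd}, rng, max(n_sites, 1))
    t = df["years_to_expected_onset"].to_numpy()
    mean = (
        baseline
        + pre_slope * t
        + slope_change * np.where(t > knot, t - knot, 0.0)
        + level_change * (t > knot)
    )
    u_site = {f"site{j + 1}": rng.normal(0, site_sd) for j in range(max(n_sites, 1))}
    u_gene = {g: rng.normal(0, gene_sd) for g in GENE_LABELS}
    df["outcome"] = (
        mean
        + df["site"].map(u_site).to_numpy()
        + df["gene"].map(u_gene).to_numpy()
        + rng.normal(0, noise_sd, len(df))
    )
    return df


def simulate_regional_strength_table(
    n_gene_negative: int = 80,
    n_carrier: int = 68,
    n_ftd: int = 24,
    *,
    n_regions: int = 90,
    hub_fraction: float = 0.10,
    nonhub_mean: float = 1.4,
    hub_gap: float = 0.8,
    hub_attack_ftd: float = 1.0,
    subject_sd: float = 0.15,
    noise_sd: float = 0.25,
    n_sites: int = 5,
    site_sd: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Subject x region nodal strengths with hub structure and optional FTD hub attack.

    Hubs exceed non-hubs by ``hub_gap``; in the FTD group hub strengths are
    multiplied by ``hub_attack_ftd`` (< 1 weakens hubs, shrinking the
    hub-minus-nonhub gap).  Rows carry hub_flag, subject metadata, and a
    shared subject intercept, matching the regional analysis layout.
    """
    rng = np.random.default_rng(seed)
    meta = _metadata_frame(
        {"gene_negative": n_gene_negative, "carrier": n_carrier, "ftd": n_ftd}, rng, n_sites
    )
    n_hub = max(1, int(round(hub_fraction * n_regions)))
    hub_flag = np.zeros(n_regions, dtype=bool)
    hub_flag[np.linspace(0, n_regions - 1, n_hub).round().astype(int)] = True
    u_site = {f"site{j + 1}": rng.normal(0, site_sd) for j in range(n_sites)}
    frames = []
    for _, row in meta.iterrows():
        u_subj = rng.normal(0, subject_sd)
        mean = np.where(hub_flag, nonhub_mean + hub_gap, nonhub_mean).astype(float)
        if row["group"] == "ftd":
            mean = np.where(hub_flag, mean * hub_attack_ftd, mean)
        out = mean + u_subj + u_site[row["site"]] + rng.normal(0, noise_sd, n_regions)
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": row["subject_id"],
                    "group": row["group"],
                    "age": row["age"],
                    "site": row["site"],
                    "gene": row["gene"],
                    "region": np.arange(n_regions),
                    "hub_flag": hub_flag,
                    "outcome": out,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
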