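"""Synthetic three-group cohort with planted rich-club structure.

The generator emulates the data layout of a resting-state connectome
study of post-stroke cognitive impairment: a healthy-control group and
two patient groups (hemorrhagic and infarct stroke), each subject
contributing a 116-parcel x 240-time-point BOLD-like series (TR 2 s),
two 30-point cognition scores (MMSE, MoCA), and — for patients — a 3D
lesion volume.

Ground truth is a weighted parcel-pair matrix with three bands: a
densely coupled 17-node core (core-core weight ``w_core``), core-to-
periphery coupling ``w_feeder``, and periphery-periphery coupling
``w_local``.  Patient groups have the feeder and local bands multiplied
by attenuation factors ``delta_feeder`` / ``delta_local`` *before*
sampling, so the planted group effect is a true distributional
difference, not a post-hoc edit of the sampled series.  Behavior scores
are linearly coupled to each subject's attenuation, and lesion geometry
and intensity scale with it, giving every downstream correlation stage a
known sign to recover.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import signal

from .connectome import TimeSeriesPanel, _bandpass_sos, write_panel_tsv, read_panel_tsv
from .lesion_features import LesionVolume, generate_lesion, save_lesion, load_lesion

__all__ = [
    "GROUPS", "PATIENT_GROUPS", "MOCA_BASELINE", "MMSE_BASELINE",
    "CohortSpec", "SubjectRecord",
    "build_ground_truth", "generate_cohort", "planted_core_graph",
    "write_cohort", "read_cohort",
]

GROUPS = ("HC", "hPSCI", "iPSCI")
PATIENT_GROUPS = ("hPSCI", "iPSCI")

# group-level behavior baselines (30-point scales)
MOCA_BASELINE = {"HC": 29.10, "hPSCI": 16.62, "iPSCI": 15.48}
MMSE_BASELINE = {"HC": 29.33, "hPSCI": 20.69, "iPSCI": 18.57}


@dataclass
class CohortSpec:
    """Parameters of the synthetic cohort.

    Attenuation factors may be a single float (applied to both patient
    groups) or a mapping from patient-group name to a factor; healthy
    controls are never attenuated.  ``subject_jitter`` is the half-width
    of a uniform per-subject perturbation of the group attenuation, which
    creates the between-subject variance that behavior and lesion
    couplings act on.
    """

    n_nodes: int = 116
    group_sizes: tuple[int, int, int] = (21, 16, 21)
    n_timepoints: int = 240
    tr_seconds: float = 2.0
    core_size: int = 17
    w_core: float = 0.85
    w_feeder: float = 0.35
    w_local: float = 0.35
    delta_feeder: float | Mapping[str, float] = 0.7
    delta_local: float | Mapping[str, float] = 0.7
    subject_jitter: float = 0.1
    behavior_beta: float = 8.0
    behavior_noise_sd: float = 1.0
    noise_sd: float = 0.0
    weight_jitter_frac: float = 0.1
    band_low_hz: float = 0.01
    band_high_hz: float = 0.08
    lesion_grid: tuple[int, int, int] = (40, 40, 40)
    lesion_spacing_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    seed: int = 0

    def validate(self) -> None:
        if self.n_nodes < 2:
            raise ValueError("n_nodes must be >= 2")
        if len(self.group_sizes) != len(GROUPS):
            raise ValueError(f"group_sizes must have {len(GROUPS)} entries")
        if sum(self.group_sizes) == 0:
            raise ValueError("group_sizes sum to 0")
        if any(n < 2 for n in self.group_sizes):
            raise ValueError("every group needs at least 2 subjects")
        if self.n_timepoints < 20:
            raise ValueError("n_timepoints < 20 is too short to estimate "
                             "correlations")
        if not (0 < self.core_size < self.n_nodes):
            raise ValueError("core_size must be in (0, n_nodes)")
        if not (0 <= self.w_local <= self.w_feeder <= self.w_core < 1):
            raise ValueError("need 0 <= w_local <= w_feeder <= w_core < 1")
        for g in PATIENT_GROUPS:
            for d in (self.delta_for(g, "feeder"), self.delta_for(g, "local")):
                if not (0 <= d <= 1):
                    raise ValueError("attenuation factors must lie in [0, 1]")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if self.band_high_hz >= 0.5 / self.tr_seconds:
            raise ValueError("band_high_hz must be below Nyquist")

    def delta_for(self, group: str, kind: str) -> float:
        if group == "HC":
            return 1.0
        value = self.delta_feeder if kind == "feeder" else self.delta_local
        if isinstance(value, Mapping):
            return float(value[group])
        return float(value)


@dataclass
class SubjectRecord:
    """One synthetic subject with its planted ground truth attached."""

    subject_id: str
    group: str
    series: TimeSeriesPanel
    mmse: float
    moca: float
    lesion: LesionVolume | None = None
    attenuation: float = 0.0          # 1 - mean applied delta (ground truth)
    delta_feeder: float = 1.0
    delta_local: float = 1.0

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if not (0 <= self.mmse <= 30 and 0 <= self.moca <= 30):
            raise ValueError("behavior scores must lie in [0, 30]")
        if self.group == "HC" and self.lesion is not None:
            raise ValueError("healthy controls have no lesion")


def _pair_masks(n_nodes: int, core: np.ndarray):
    """Boolean matrices selecting core-core, core-periphery, periphery pairs."""
    is_core = np.zeros(n_nodes, dtype=bool)
    is_core[core] = True
    cc = np.outer(is_core, is_core)
    pp = np.outer(~is_core, ~is_core)
    fd = ~cc & ~pp
    off = ~np.eye(n_nodes, dtype=bool)
    return cc & off, fd & off, pp & off


def build_ground_truth(spec: CohortSpec,
                       rng: np.random.Generator | None = None
                       ) -> tuple[np.ndarray, np.ndarray]:
    """The banded weight matrix and the planted core node set.

    Core-core pairs get ``w_core``, core-periphery ``w_feeder``, and
    periphery-periphery ``w_local``, each plus a small symmetric uniform
    jitter (default +-10% of the smallest gap between weight bands, so
    bands never overlap and degree ties are rare).  Zero diagonal.
    """
    spec.validate()
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0]))
    n = spec.n_nodes
    core = np.arange(spec.core_size)
    cc, fd, pp = _pair_masks(n, core)
    w = np.zeros((n, n))
    w[cc] = spec.w_core
    w[fd] = spec.w_feeder
    w[pp] = spec.w_local
    gaps = [g for g in (spec.w_core - spec.w_feeder,
                        spec.w_feeder - spec.w_local) if g > 0]
    amp = spec.weight_jitter_frac * (min(gaps) if gaps else 0.05)
    iu, ju = np.triu_indices(n, k=1)
    jitter = rng.uniform(-amp, amp, size=len(iu))
    w[iu, ju] += jitter
    w[ju, iu] = w[iu, ju]
    np.fill_diagonal(w, 0.0)
    return w, core


def _loaded_cholesky(weights: np.ndarray) -> tuple[np.ndarray, float]:
    """Cholesky factor of weights + I + lambda*I for the smallest workable
    diagonal loading lambda in {1e-6 * 2^j}."""
    c = weights + np.eye(len(weights))
    lam = 0.0
    for j in range(64):
        try:
            return np.linalg.cholesky(c + lam * np.eye(len(c))), lam
        except np.linalg.LinAlgError:
            lam = 1e-6 * 2 ** j
    raise np.linalg.LinAlgError(
        f"covariance not positive definite even with loading {lam:g}")


def implied_correlation(weights: np.ndarray) -> np.ndarray:
    """Correlation matrix implied by the (loaded) ground-truth covariance."""
    _, lam = _loaded_cholesky(weights)
    cov = weights + (1.0 + lam) * np.eye(len(weights))
    d = np.sqrt(np.diag(cov))
    corr = cov / np.outer(d, d)
    np.fill_diagonal(corr, 0.0)
    return corr


def sample_series(chol: np.ndarray, spec: CohortSpec,
                  rng: np.random.Generator) -> np.ndarray:
    """One parcel x time series: correlated Gaussian draws, band-limited.

    The same zero-phase band-pass is applied to every parcel, which
    leaves the cross-parcel correlation structure intact while giving the
    series the temporal band of the analysis (0.01-0.08 Hz by default).
    """
    eps = rng.standard_normal((chol.shape[0], spec.n_timepoints))
    series = chol @ eps
    sos = _bandpass_sos(spec.band_low_hz, spec.band_high_hz,
                        1.0 / spec.tr_seconds)
    series = signal.sosfiltfilt(sos, series, axis=1)
    if spec.noise_sd > 0:
        series = series + rng.normal(0.0, spec.noise_sd, size=series.shape)
    return series


def _attenuated_weights(w: np.ndarray, core: np.ndarray,
                        d_feeder: float, d_local: float) -> np.ndarray:
    cc, fd, pp = _pair_masks(len(w), core)
    out = w.copy()
    out[fd] *= d_feeder
    out[pp] *= d_local
    return out


def generate_cohort(spec: CohortSpec) -> list[SubjectRecord]:
    """The full synthetic cohort, byte-identical for identical specs.

    Per subject: the group's attenuation factors (plus a uniform
    per-subject jitter, clipped to [0, 1]) scale the feeder and local
    weight bands; the series is sampled from the resulting covariance and
    band-limited; behavior scores are the group baseline minus
    ``behavior_beta`` times the subject's attenuation plus Gaussian
    noise, clipped to [0, 30]; patients additionally get an ellipsoidal
    lesion whose radii and signal intensity grow with the attenuation.

    One *shared* diagonal loading — the smallest that renders every
    subject's attenuated covariance positive definite — is applied to the
    whole cohort.  A per-subject loading would alter the diagonal (and
    hence every correlation) differently across groups, planting a
    spurious global group effect on edges that are nominally
    unattenuated.
    """
    spec.validate()
    w, core = build_ground_truth(spec)
    # pass 1: per-subject attenuation factors and the loading they need
    deltas: list[tuple[float, float]] = []
    lam_max = _loaded_cholesky(w)[1]
    subj_idx = 0
    for group, n_subj in zip(GROUPS, spec.group_sizes):
        for _ in range(n_subj):
            rng_d = np.random.default_rng(
                np.random.SeedSequence([spec.seed, 1, subj_idx, 0]))
            if group == "HC":
                df = dl = 1.0
            else:
                df = float(np.clip(spec.delta_for(group, "feeder")
                                   + rng_d.uniform(-spec.subject_jitter,
                                                   spec.subject_jitter), 0, 1))
                dl = float(np.clip(spec.delta_for(group, "local")
                                   + rng_d.uniform(-spec.subject_jitter,
                                                   spec.subject_jitter), 0, 1))
                lam_max = max(lam_max, _loaded_cholesky(
                    _attenuated_weights(w, core, df, dl))[1])
            deltas.append((df, dl))
            subj_idx += 1
    # pass 2: sample every subject under the shared loading
    records: list[SubjectRecord] = []
    subj_idx = 0
    eye = np.eye(spec.n_nodes)
    for group, n_subj in zip(GROUPS, spec.group_sizes):
        for i in range(n_subj):
            rng = np.random.default_rng(
                np.random.SeedSequence([spec.seed, 1, subj_idx, 1]))
            df, dl = deltas[subj_idx]
            atten = 1.0 - 0.5 * (df + dl)
            cov = _attenuated_weights(w, core, df, dl) + (1.0 + lam_max) * eye
            chol = np.linalg.cholesky(cov)
            series = sample_series(chol, spec, rng)
            moca = float(np.clip(
                MOCA_BASELINE[group] - spec.behavior_beta * atten
                + rng.normal(0.0, spec.behavior_noise_sd), 0, 30))
            mmse = float(np.clip(
                MMSE_BASELINE[group] - spec.behavior_beta * atten
                + rng.normal(0.0, spec.behavior_noise_sd), 0, 30))
            lesion = None
            if group != "HC":
                lesion = _patient_lesion(spec, group, atten, rng)
            records.append(SubjectRecord(
                subject_id=f"{group}_{i:02d}",
                group=group,
                series=TimeSeriesPanel(series, spec.tr_seconds),
                mmse=mmse, moca=moca, lesion=lesion,
                attenuation=atten, delta_feeder=df, delta_local=dl))
            subj_idx += 1
    return records


def _patient_lesion(spec: CohortSpec, group: str, atten: float,
                    rng: np.random.Generator) -> LesionVolume:
    """Ellipsoidal lesion whose size and signal scale with attenuation.

    Infarct lesions are drawn larger than hemorrhagic ones, echoing the
    study population this generator emulates; both scale with the
    subject's planted attenuation so radiomic-connectivity correlations
    have a known sign.
    """
    shape = spec.lesion_grid
    base = 14.0 if group == "iPSCI" else 10.0  # mm
    scale = 0.6 + atten
    radii = tuple(base * scale * f for f in (1.0, 0.85, 0.7))
    center = tuple(s / 2 + rng.uniform(-2, 2) for s in shape)
    return generate_lesion(
        shape=shape, center=center, radii_mm=radii,
        intensity_mean=80.0 + 40.0 * atten, intensity_sd=10.0,
        spacing_mm=spec.lesion_spacing_mm,
        background_mean=20.0, background_sd=5.0, seed=rng)


def planted_core_graph(
    n_nodes: int = 116,
    density: float = 0.10,
    core_size: int = 17,
    core_p: float = 0.9,
    feeder_frac: float = 0.18,
    branch_decay: float = 0.97,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """A binary graph with a planted dense core on heavy-tailed degrees.

    Three ingredients reproduce the connectome motifs the rich-club
    measure is sensitive to:

    * **core**: the first ``core_size`` nodes are pairwise connected with
      probability ``core_p`` — denser than any degree-matched null, which
      drives phi_norm above 1 at mid-to-high k;
    * **feeders**: a ``feeder_frac`` share of the remaining edge budget
      links core nodes to the best-connected periphery nodes;
    * **local periphery**: the rest of the budget forms a chain lattice —
      periphery node at rank r links to its next ``b_r`` neighbors with
      ``b_r`` decaying geometrically (``branch_decay``) along the rank.
      This yields a long low-degree tail whose edges join other
      low-degree nodes; a degree-preserving null reallocates those edges
      toward hubs, so phi_norm exceeds 1 at low k as well, matching the
      low-degree rich-club enrichment seen in brain graphs.

    The total edge count is ``round(density * N(N-1)/2)``.  Fully seeded.
    """
    if not (0 < density <= 1):
        raise ValueError("density must be in (0, 1]")
    if not (0 < core_size < n_nodes):
        raise ValueError("core_size must be in (0, n_nodes)")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    m_total = n_nodes * (n_nodes - 1) // 2
    m_target = int(np.floor(density * m_total + 0.5))
    core = np.arange(core_size)
    adj = np.zeros((n_nodes, n_nodes), dtype=np.int8)
    ci, cj = np.triu_indices(core_size, k=1)
    present = rng.random(len(ci)) < core_p
    adj[ci[present], cj[present]] = 1
    remaining = m_target - int(present.sum())
    if remaining < 0:
        raise ValueError("density too low to hold the planted core")
    n_per = n_nodes - core_size
    n_feeder = min(int(round(feeder_frac * remaining)),
                   core_size * min(30, n_per))
    n_local = remaining - n_feeder
    if n_local > n_per * (n_per - 1) // 2:
        raise ValueError("periphery too small for the requested density")

    # periphery chain lattice with geometrically decaying branch counts
    raw = branch_decay ** np.arange(n_per)
    b = np.maximum(1, np.round(raw * n_local / raw.sum())).astype(int)
    pr, ps = np.triu_indices(n_per, k=1)
    over_branch = np.maximum(0, (ps - pr) - b[pr])
    order = np.lexsort((ps, pr, over_branch))
    keep = order[:n_local]
    per = np.arange(core_size, n_nodes)
    adj[per[pr[keep]], per[ps[keep]]] = 1

    # feeder edges: core to the densest periphery ranks
    fc, fp = np.meshgrid(core, per[:min(30, n_per)], indexing="ij")
    flat = np.arange(fc.size)
    chosen = rng.choice(flat, size=n_feeder, replace=False)
    adj[fc.ravel()[chosen], fp.ravel()[chosen]] = 1

    adj |= adj.T
    np.fill_diagonal(adj, 0)
    return adj, core


# ---------------------------------------------------------------------------
# Cohort export / import (plain text + NIfTI lesions)

def write_cohort(records: list[SubjectRecord], outdir) -> Path:
    """One series TSV per subject, a manifest TSV, NIfTI lesion volumes."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in records:
        series_path = outdir / f"{rec.subject_id}_series.tsv"
        write_panel_tsv(rec.series, series_path)
        lesion_path = mask_path = ""
        if rec.lesion is not None:
            lesion_path = f"{rec.subject_id}_lesion.nii.gz"
            mask_path = f"{rec.subject_id}_mask.nii.gz"
            save_lesion(rec.lesion, outdir / lesion_path, outdir / mask_path)
        rows.append({
            "subject_id": rec.subject_id, "group": rec.group,
            "mmse": rec.mmse, "moca": rec.moca,
            "series_path": series_path.name,
            "lesion_path": lesion_path, "mask_path": mask_path,
            "tr_seconds": rec.series.tr_seconds,
        })
    manifest = outdir / "manifest.tsv"
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False,
                              float_format="%.10g")
    return manifest


def read_cohort(cohort_dir) -> list[SubjectRecord]:
    """Load a cohort previously written by :func:`write_cohort`."""
    cohort_dir = Path(cohort_dir)
    manifest = pd.read_csv(cohort_dir / "manifest.tsv", sep="\t",
                           keep_default_na=False)
    records = []
    for _, row in manifest.iterrows():
        panel = read_panel_tsv(cohort_dir / row["series_path"],
                               float(row["tr_seconds"]))
        lesion = None
        if row["lesion_path"]:
            lesion = load_lesion(cohort_dir / row["lesion_path"],
                                 cohort_dir / row["mask_path"])
        records.append(SubjectRecord(
            subject_id=str(row["subject_id"]), group=str(row["group"]),
            series=panel, mmse=float(row["mmse"]), moca=float(row["moca"]),
            lesion=lesion))
    return records
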