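"""End-to-end analysis: cohort -> connectomes -> rich club -> statistics.

A single configured, seeded run produces tidy TSV tables for every
intermediate quantity and a JSON report whose numbers are all traceable
to those tables.  Reruns with the same configuration are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import group_analysis as ga
from . import richclub as rc
from .connectome import correlation_matrix, preprocess, sparsity_sweep
from .lesion_features import all_features, features_frame
from .synthetic_cohort import (GROUPS, PATIENT_GROUPS, CohortSpec,
                               generate_cohort)

log = logging.getLogger(__name__)

__all__ = ["AnalysisConfig", "run"]


@dataclass
class AnalysisConfig:
    """Everything one run needs; defaults follow standard practice for
    this analysis (46-level sparsity sweep 0.05-0.5, 10 discarded volumes,
    0.01-0.08 Hz band, top 15% rich nodes, 1000-graph null ensemble,
    alpha = q = 0.05)."""

    cohort: CohortSpec = field(default_factory=CohortSpec)
    s_min: float = 0.05
    s_max: float = 0.5
    s_step: float = 0.01
    discard_n: int = 10
    band_low_hz: float = 0.01
    band_high_hz: float = 0.08
    rich_fraction: float = 0.15
    n_null: int = 1000
    n_swap_per_edge: int = 10
    alpha: float = 0.05
    q: float = 0.05
    k_window: tuple[int, int] = (2, 8)
    top_m_nodes: int = 2
    seed: int = 0

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort"] = dataclasses.asdict(self.cohort)
        return _listify(d)

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        d = dict(d)
        cohort = d.pop("cohort", {})
        spec = CohortSpec(**{k: _tupleize(k, v) for k, v in cohort.items()})
        cfg = cls(cohort=spec, **{k: _tupleize(k, v) for k, v in d.items()})
        return cfg

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def test_profile(cls, seed: int = 0) -> "AnalysisConfig":
        """A reduced configuration that completes in minutes: a smaller
        cohort and node count, five sparsity levels, 100 nulls."""
        return cls(
            cohort=CohortSpec(n_nodes=40, group_sizes=(6, 5, 6),
                              n_timepoints=120, core_size=6, seed=seed),
            s_min=0.1, s_max=0.3, s_step=0.05,
            n_null=100, seed=seed)


_TUPLE_FIELDS = {"group_sizes", "k_window", "lesion_grid",
                 "lesion_spacing_mm"}


def _listify(obj):
    if isinstance(obj, dict):
        return {k: _listify(v) for k, v in obj.items()}
    if isinstance(obj, tuple):
        return [_listify(v) for v in obj]
    return obj


def _tupleize(key, value):
    if key in _TUPLE_FIELDS and isinstance(value, list):
        return tuple(value)
    return value


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if not np.isfinite(v) else round(v, 10)
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def run(config: AnalysisConfig, out_dir=None) -> dict:
    """Execute every stage and return (and optionally write) the report.

    Stages: generate cohort; preprocess each subject's series; correlate;
    sparsity sweep; per-sparsity normalized rich-club profiles (averaged
    across the sweep into one summary curve per subject); rich-node
    selection on the grand-mean degree; edge classification; edgewise and
    curvewise group statistics with BH-FDR; aberrant-node ranking with
    nodal-efficiency statistics; behavioral and radiomic correlations.
    """
    cohort_spec = dataclasses.replace(config.cohort, seed=config.seed)
    stage = "generate_cohort"
    try:
        records = generate_cohort(cohort_spec)
        tables: dict[str, pd.DataFrame] = {}

        stage = "connectome"
        stacks, z_vectors, labels = _connectome_stage(records, config)
        n_nodes = cohort_spec.n_nodes
        iu, ju = np.triu_indices(n_nodes, k=1)

        stage = "richclub"
        summary_by_subject, mean_degree, efficiency = _richclub_stage(
            records, stacks, config)
        rich = rc.select_rich_nodes(mean_degree, config.rich_fraction)
        pair_class = rc.classify_pairs(n_nodes, rich)

        stage = "edgewise_stats"
        z_by_group = {
            g: np.stack([z_vectors[r.subject_id] for r in records
                         if r.group == g])
            for g in GROUPS}
        edge_stats = ga.edgewise_group_stats(
            z_by_group, alpha=config.alpha, q=config.q)
        edge_stats.insert(0, "j", ju)
        edge_stats.insert(0, "i", iu)
        edge_stats.insert(2, "edge_class", pair_class)
        tables["edge_stats"] = edge_stats

        stage = "curvewise_stats"
        kmax = max(len(s) for s in summary_by_subject.values())
        phinorm_by_group = {
            g: np.stack([_pad(summary_by_subject[r.subject_id], kmax)
                         for r in records if r.group == g])
            for g in GROUPS}
        curve_stats = ga.curvewise_phinorm_stats(
            phinorm_by_group, alpha=config.alpha, q=config.q)
        tables["phinorm_stats"] = curve_stats

        stage = "aberrant_nodes"
        node_counts, top_nodes = ga.aberrant_node_frequency(
            edge_stats, iu, ju, n_nodes, list(PATIENT_GROUPS),
            top_m=config.top_m_nodes)
        tables["node_frequency"] = node_counts
        eff_stats = _efficiency_stats(records, efficiency, top_nodes)
        tables["efficiency_stats"] = eff_stats

        stage = "behavior_correlation"
        behav = _behavior_stage(records, edge_stats, z_vectors, config)
        tables["behavior_correlation"] = behav

        stage = "radiomics"
        feats, radiomic_corr = _radiomic_stage(
            records, edge_stats, z_vectors, summary_by_subject, config)
        tables["lesion_features"] = feats
        tables["radiomic_correlation"] = radiomic_corr
    except Exception as exc:  # annotate which stage failed
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    report = _build_report(config, records, labels, rich, edge_stats,
                           curve_stats, phinorm_by_group, node_counts,
                           top_nodes, eff_stats, behav, radiomic_corr)
    if out_dir is not None:
        _write_outputs(out_dir, config, tables, report)
    return report


def _connectome_stage(records, config):
    stacks = {}
    z_vectors = {}
    labels = None
    for rec in records:
        panel = preprocess(rec.series, config.discard_n,
                           config.band_low_hz, config.band_high_hz)
        conn = correlation_matrix(panel)
        labels = conn.parcel_labels
        iu, ju = np.triu_indices(conn.n_parcels, k=1)
        z_vectors[rec.subject_id] = conn.z[iu, ju]
        stacks[rec.subject_id] = sparsity_sweep(
            conn, config.s_min, config.s_max, config.s_step)
    return stacks, z_vectors, labels


def _richclub_stage(records, stacks, config):
    """Per-subject summary phi_norm curve (mean across the sweep), the
    grand-mean binarized degree, and sweep-mean nodal efficiency."""
    summary = {}
    degree_sum = None
    efficiency = {}
    ss = np.random.SeedSequence([config.seed, 3])
    subject_seeds = ss.generate_state(len(records))
    for rec, sub_seed in zip(records, subject_seeds):
        stack = stacks[rec.subject_id]
        profiles = []
        effs = []
        degs = []
        for si in range(len(stack)):
            g = rc.BinaryGraph(stack[si])
            profiles.append(rc.normalized_rich_club(
                g, n_null=config.n_null,
                n_swap_per_edge=config.n_swap_per_edge,
                seed=int(sub_seed) + si))
            metrics = rc.nodal_efficiency(g)
            effs.append(metrics.efficiency)
            degs.append(metrics.degree)
        summary_df = rc.summarize_profiles(profiles)
        summary[rec.subject_id] = summary_df["phi_norm"].to_numpy()
        mean_deg = np.mean(degs, axis=0)
        degree_sum = mean_deg if degree_sum is None else degree_sum + mean_deg
        efficiency[rec.subject_id] = np.mean(effs, axis=0)
    mean_degree = degree_sum / len(records)
    return summary, mean_degree, efficiency


def _pad(v: np.ndarray, k: int) -> np.ndarray:
    out = np.full(k, np.nan)
    out[:len(v)] = v
    return out


def _efficiency_stats(records, efficiency, top_nodes):
    nodes = sorted({n for ns in top_nodes.values() for n in ns})
    rows = []
    for node in nodes:
        by_group = [np.array([efficiency[r.subject_id][node]
                              for r in records if r.group == g])[:, None]
                    for g in GROUPS]
        f, p = ga.one_way_anova(by_group)
        row = {"node": node, "F": float(f[0]), "p": float(p[0])}
        for g, vals in zip(GROUPS, by_group):
            row[f"mean_{g}"] = float(vals.mean())
        rows.append(row)
    return pd.DataFrame(rows)


def _behavior_stage(records, edge_stats, z_vectors, config, max_edges=20):
    """Correlate each contrast's strongest significant decreased edges with
    MMSE / MoCA within that patient group."""
    frames = []
    for g in PATIENT_GROUPS:
        hit = edge_stats[edge_stats[f"sig_{g}"]
                         & edge_stats[f"decreased_{g}"]].copy()
        if hit.empty:
            continue
        hit = hit.reindex(hit[f"t_{g}"].abs()
                          .sort_values(ascending=False).index)[:max_edges]
        subjects = [r for r in records if r.group == g]
        values = pd.DataFrame(
            {f"edge_{int(r.i)}_{int(r.j)}":
             [z_vectors[s.subject_id][idx] for s in subjects]
             for idx, r in zip(hit.index, hit.itertuples())})
        scores = pd.DataFrame({"mmse": [s.mmse for s in subjects],
                               "moca": [s.moca for s in subjects]})
        tab = ga.behavior_correlation(values, scores, fdr_q=config.q)
        tab.insert(0, "contrast", g)
        frames.append(tab)
    if not frames:
        return pd.DataFrame(columns=["contrast", "feature", "score",
                                     "n", "r", "p", "note", "q"])
    return pd.concat(frames, ignore_index=True)


def _radiomic_stage(records, edge_stats, z_vectors, summary_by_subject,
                    config):
    """Lesion features per patient, correlated with the subject's mean z
    over significant decreased local edges and with low-k phi_norm."""
    feats = {r.subject_id: all_features(r.lesion)
             for r in records if r.lesion is not None}
    feat_df = features_frame(feats) if feats else pd.DataFrame()
    frames = []
    k_lo, k_hi = config.k_window
    for g in PATIENT_GROUPS:
        subjects = [r for r in records if r.group == g and r.lesion is not None]
        if len(subjects) < 3:
            continue
        hit = edge_stats[edge_stats[f"sig_{g}"]
                         & edge_stats[f"decreased_{g}"]
                         & (edge_stats["edge_class"] == "local")]
        values = {}
        if not hit.empty:
            idx = hit.index.to_numpy()
            values["mean_decreased_local_z"] = [
                float(np.mean(z_vectors[s.subject_id][idx])) for s in subjects]
        for k in range(k_lo, k_hi + 1):
            col = []
            for s in subjects:
                curve = summary_by_subject[s.subject_id]
                col.append(curve[k - 1] if k - 1 < len(curve) else np.nan)
            if np.isfinite(col).sum() >= 3:
                values[f"phi_norm_k{k}"] = col
        if not values:
            continue
        vdf = pd.DataFrame(values)
        fdf = pd.DataFrame([feats[s.subject_id] for s in subjects])
        tab = ga.behavior_correlation(vdf, fdf, fdr_q=config.q)
        tab = tab.rename(columns={"feature": "network_measure",
                                  "score": "lesion_feature"})
        tab.insert(0, "contrast", g)
        frames.append(tab)
    corr = (pd.concat(frames, ignore_index=True) if frames
            else pd.DataFrame(columns=["contrast", "network_measure",
                                       "lesion_feature", "n", "r", "p",
                                       "note", "q"]))
    return feat_df, corr


def _build_report(config, records, labels, rich, edge_stats, curve_stats,
                  phinorm_by_group, node_counts, top_nodes, eff_stats,
                  behav, radiomic_corr) -> dict:
    sig_counts = {}
    for g in PATIENT_GROUPS:
        hit = edge_stats[edge_stats[f"sig_{g}"] & edge_stats[f"decreased_{g}"]]
        sig_counts[g] = {c: int((hit["edge_class"] == c).sum())
                         for c in rc.EDGE_CLASSES}
    windows = {g: ga.significant_window(curve_stats, g)
               for g in PATIENT_GROUPS}
    curves = {}
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for g, arr in phinorm_by_group.items():
            curves[g] = np.nanmean(arr, axis=0)
    report = {
        "package_version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_subjects": {g: sum(r.group == g for r in records) for g in GROUPS},
        "rich_nodes": {
            "indices": [int(i) for i in rich],
            "labels": [labels[i] for i in rich] if labels else [],
        },
        "phi_norm_curves": {g: curves[g] for g in GROUPS},
        "significant_k_window": {
            g: (list(w) if w is not None else None)
            for g, w in windows.items()},
        "significant_decreased_edges": sig_counts,
        "top_aberrant_nodes": {
            g: [{"node": int(n),
                 "label": labels[n] if labels else str(n),
                 "count": int(node_counts.loc[n, f"count_{g}"])}
                for n in ns]
            for g, ns in top_nodes.items()},
        "efficiency_stats": eff_stats.to_dict(orient="records"),
        "behavior_correlations": {
            "n_pairs": int(len(behav)),
            "n_significant_positive": int(
                ((behav["q"] < config.q) & (behav["r"] > 0)).sum())
            if len(behav) else 0,
        },
        "radiomic_correlations": {
            "n_pairs": int(len(radiomic_corr)),
            "n_significant": int((radiomic_corr["q"] < config.q).sum())
            if len(radiomic_corr) else 0,
        },
    }
    return _jsonable(report)


def _write_outputs(out_dir, config, tables: dict[str, pd.DataFrame],
                   report: dict) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    header = (f"# richconn {__version__} config_hash={config.config_hash()} "
              f"seed={config.seed}\n")
    for name, df in tables.items():
        path = out / f"{name}.tsv"
        with open(path, "w") as fh:
            fh.write(header)
            df.to_csv(fh, sep="\t", index=False, float_format="%.10g")
    config.to_yaml(out / "config.yaml")
    (out / "report.json").write_text(
        json.dumps(report, sort_keys=True, indent=2) + "\n")
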