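"""Functional connectome construction from parcel-level time series.

The processing chain mirrors standard resting-state practice: discard the
initial volumes, linearly detrend each parcel's time course, band-pass to
the low-frequency band (default 0.01-0.08 Hz), correlate every parcel pair
(Pearson r, Fisher z), and binarize the correlation matrix at a sweep of
proportional sparsity thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .atlas import default_labels

__all__ = [
    "TimeSeriesPanel",
    "FunctionalConnectome",
    "GraphStack",
    "preprocess",
    "correlation_matrix",
    "threshold_by_sparsity",
    "sparsity_sweep",
    "read_panel_tsv",
    "write_panel_tsv",
    "write_matrix_tsv",
    "read_matrix_tsv",
]

_Z_CLIP = 1.0 - 1e-15  # |r| is clipped here before arctanh


@dataclass
class TimeSeriesPanel:
    """A parcel x time matrix of BOLD-like signals for one subject.

    Parameters
    ----------
    data : ndarray, shape (n_parcels, n_timepoints)
    tr_seconds : float
        Sampling interval (repetition time) in seconds.
    parcel_labels : list of str, optional
        Defaults to the AAL-116 names when there are 116 rows.
    """

    data: np.ndarray
    tr_seconds: float
    parcel_labels: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("panel data must be 2-D (parcels x time)")
        if self.data.shape[0] < 2:
            raise ValueError("panel needs at least 2 parcels")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("panel contains non-finite values")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if self.parcel_labels is None:
            self.parcel_labels = default_labels(self.data.shape[0])
        else:
            self.parcel_labels = list(self.parcel_labels)
        if len(self.parcel_labels) != self.data.shape[0]:
            raise ValueError("number of labels must equal number of parcels")
        if len(set(self.parcel_labels)) != len(self.parcel_labels):
            raise ValueError("parcel labels must be unique")

    @property
    def n_parcels(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]

    @property
    def fs_hz(self) -> float:
        return 1.0 / self.tr_seconds


@dataclass
class FunctionalConnectome:
    """Pearson correlation matrix ``r`` and its Fisher transform ``z``.

    ``r`` is exactly symmetric with zero diagonal; ``z = arctanh(r)`` with
    ``|r|`` clipped just below 1 so degenerate (perfectly correlated)
    inputs stay finite.
    """

    r: np.ndarray
    z: np.ndarray
    parcel_labels: list[str]

    def __post_init__(self) -> None:
        r = np.asarray(self.r, dtype=float)
        if r.ndim != 2 or r.shape[0] != r.shape[1]:
            raise ValueError("r must be square")
        if not np.array_equal(r, r.T):
            raise ValueError("r must be exactly symmetric")
        if np.any(np.abs(r) > 1):
            raise ValueError("|r| must not exceed 1")
        if np.any(np.diag(r) != 0):
            raise ValueError("diagonal of r must be exactly 0")

    @property
    def n_parcels(self) -> int:
        return self.r.shape[0]


@dataclass
class GraphStack:
    """Binarized adjacency matrices across a sparsity sweep (one subject).

    Adjacency matrices are nested: the edge set at a smaller sparsity is a
    subset of the edge set at any larger sparsity, because every threshold
    cuts the same correlation ranking.
    """

    sparsities: np.ndarray
    adjacency: np.ndarray  # (n_sparsities, N, N) of 0/1
    parcel_labels: list[str]

    def __len__(self) -> int:
        return len(self.sparsities)

    def __getitem__(self, i: int) -> np.ndarray:
        return self.adjacency[i]


def preprocess(
    panel: TimeSeriesPanel,
    discard_n: int = 10,
    band_low_hz: float = 0.01,
    band_high_hz: float = 0.08,
) -> TimeSeriesPanel:
    """Discard initial volumes, detrend, and band-pass filter a panel.

    The filter is a fourth-order zero-phase Butterworth band-pass
    (``sosfiltfilt``), applied after removing each row's linear trend.

    Raises
    ------
    ValueError
        If ``discard_n`` leaves no data or the band is invalid relative to
        the Nyquist frequency ``1/(2*tr)``.
    """
    nyq = 0.5 * panel.fs_hz
    if discard_n < 0 or discard_n >= panel.n_timepoints:
        raise ValueError(
            f"discard_n={discard_n} must be in [0, {panel.n_timepoints})"
        )
    if not (0 <= band_low_hz < band_high_hz):
        raise ValueError("need 0 <= band_low_hz < band_high_hz")
    if band_high_hz >= nyq:
        raise ValueError(
            f"band_high_hz={band_high_hz} must be below the Nyquist "
            f"frequency {nyq:.6g} Hz implied by tr={panel.tr_seconds} s"
        )
    data = panel.data[:, discard_n:]
    data = signal.detrend(data, axis=1, type="linear")
    sos = _bandpass_sos(band_low_hz, band_high_hz, panel.fs_hz)
    data = signal.sosfiltfilt(sos, data, axis=1)
    return TimeSeriesPanel(data, panel.tr_seconds, list(panel.parcel_labels))


def _bandpass_sos(low_hz: float, high_hz: float, fs_hz: float) -> np.ndarray:
    # order 2 per edge -> fourth-order band-pass overall
    return signal.butter(2, [low_hz, high_hz], btype="bandpass",
                         fs=fs_hz, output="sos")


def correlation_matrix(panel: TimeSeriesPanel) -> FunctionalConnectome:
    """Pearson correlation of every parcel pair, with Fisher z.

    Raises
    ------
    ValueError
        If any parcel has zero variance (named in the message).
    """
    sd = panel.data.std(axis=1)
    if np.any(sd == 0):
        bad = [panel.parcel_labels[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"zero-variance parcel(s): {', '.join(bad)}")
    r = np.corrcoef(panel.data)
    r = np.clip(r, -1.0, 1.0)
    r = (r + r.T) / 2.0
    np.fill_diagonal(r, 0.0)
    z = np.arctanh(np.clip(r, -_Z_CLIP, _Z_CLIP))
    np.fill_diagonal(z, 0.0)
    return FunctionalConnectome(r=r, z=z, parcel_labels=list(panel.parcel_labels))


def _pair_ranking(r: np.ndarray, rank_by: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Upper-triangle pairs ordered strongest-first with a stable tie-break.

    Ties are broken by the lexicographic (i, j) pair index, which the stable
    sort provides because pairs are enumerated in lexicographic order.
    """
    n = r.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    vals = r[iu, ju]
    if rank_by == "abs":
        key = -np.abs(vals)
    elif rank_by == "signed":
        key = -vals
    else:
        raise ValueError("rank_by must be 'signed' or 'abs'")
    order = np.argsort(key, kind="stable")
    return iu[order], ju[order], vals[order]


def _edge_count(s: float, n: int) -> int:
    m_total = n * (n - 1) // 2
    return int(np.floor(s * m_total + 0.5))  # round half up, deterministic


def threshold_by_sparsity(
    conn: FunctionalConnectome, s: float, rank_by: str = "signed"
) -> np.ndarray:
    """Keep the ``round(s * N(N-1)/2)`` strongest pairs as a 0/1 graph.

    By default the ranking is by signed r, so strong negative correlations
    never enter the binary graph; pass ``rank_by='abs'`` to rank by
    magnitude instead.
    """
    if not (0 < s <= 1):
        raise ValueError("sparsity must be in (0, 1]")
    n = conn.n_parcels
    iu, ju, _ = _pair_ranking(conn.r, rank_by)
    m = _edge_count(s, n)
    adj = np.zeros((n, n), dtype=np.int8)
    adj[iu[:m], ju[:m]] = 1
    adj |= adj.T
    return adj


def sparsity_sweep(
    conn: FunctionalConnectome,
    s_min: float = 0.05,
    s_max: float = 0.5,
    step: float = 0.01,
    rank_by: str = "signed",
) -> GraphStack:
    """Binarize at every sparsity from ``s_min`` to ``s_max`` (inclusive).

    The endpoint is included up to a 1e-9 tolerance on the grid.  All
    thresholds cut one shared ranking, so the stack is nested by
    construction.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    if s_min > s_max:
        raise ValueError("s_min must not exceed s_max")
    n_steps = int(np.floor((s_max - s_min) / step + 1e-9)) + 1
    sparsities = s_min + step * np.arange(n_steps)
    if n_steps == 0:
        raise ValueError("empty sparsity sweep")
    n = conn.n_parcels
    iu, ju, _ = _pair_ranking(conn.r, rank_by)
    stack = np.zeros((n_steps, n, n), dtype=np.int8)
    for idx, s in enumerate(sparsities):
        m = _edge_count(float(s), n)
        adj = stack[idx]
        adj[iu[:m], ju[:m]] = 1
        adj |= adj.T
    return GraphStack(sparsities=sparsities, adjacency=stack,
                      parcel_labels=list(conn.parcel_labels))


# ---------------------------------------------------------------------------
# Plain-text I/O

def read_panel_tsv(path, tr_seconds: float) -> TimeSeriesPanel:
    """Read a parcels x time TSV whose first column holds parcel labels."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return TimeSeriesPanel(df.to_numpy(dtype=float), tr_seconds,
                           [str(x) for x in df.index])


def write_panel_tsv(panel: TimeSeriesPanel, path) -> None:
    df = pd.DataFrame(panel.data, index=panel.parcel_labels)
    df.to_csv(path, sep="\t", float_format="%.10g")


def write_matrix_tsv(matrix: np.ndarray, labels: list[str], path) -> None:
    pd.DataFrame(matrix, index=labels, columns=labels).to_csv(
        path, sep="\t", float_format="%.10g"
    )


def read_matrix_tsv(path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(dtype=float), [str(x) for x in df.index]
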