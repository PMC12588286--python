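"""Electrode-level analyses on offline (400-Hz) high-gamma features.

Three families of tests, each tied to the electrode grid's geometry:

* **Speech-responsive electrodes**: per-trial mean baseline (-700 to -500 ms)
  vs. the instantaneous value at every onset-window time point, paired
  t-tests with Bonferroni correction over electrodes x time points, and a
  minimum significant duration of 200 ms.

* **Discriminative electrodes**: for multi-level factors (syllable, manner of
  articulation) a spatiotemporal cluster-mass permutation test — pointwise
  one-way F statistics, suprathreshold clustering under grid adjacency,
  label-shuffle null of the maximum cluster mass — followed within surviving
  clusters by pairwise Welch t-tests (FDR), requiring >=3 separated levels
  over >=200 ms. Tone uses balanced pointwise ANOVA with Bonferroni; place of
  articulation (labial vs. lingual) a pointwise two-group Welch test.

* **Gradient saliency**: the trained decoder's cross-entropy loss is
  backpropagated to its input; per-electrode contribution = the trial-mean of
  the time-summed absolute input gradient, normalized to [0, 1], with the
  shortest descending prefix reaching 90% of the total as the selection mask.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse, stats as sps
from scipy.sparse.csgraph import connected_components
from statsmodels.stats.multitest import multipletests

from .core_io import ChannelTable, EventTable, FeatureMatrix, SyllableInventory, \
    ValidationError
from .decoder import DecoderModel, TrialSegment, one_hot, segments_to_arrays
from . import nn

logger = logging.getLogger(__name__)


@dataclass
class ElectrodeStatsConfig:
    onset_window_ms: tuple[float, float] = (-500.0, 500.0)
    baseline_window_ms: tuple[float, float] = (-700.0, -500.0)
    balanced_n: int = 1000
    alpha: float = 0.05
    min_sig_duration_ms: float = 200.0
    cluster_f_threshold: float = 3.0
    n_permutations: int = 1000
    adjacency_factor: float = 1.2      # x pitch: below sqrt(2), 4-connectivity
    correction: str = "fdr"            # pairwise follow-up: 'fdr' | 'bonferroni'
    min_levels: int = 3
    seed: int = 0

    def min_run_frames(self, frame_rate_hz: float) -> int:
        """The >=200-ms rule in whole frames (80 points at 400 Hz)."""
        return int(round(self.min_sig_duration_ms / 1000 * frame_rate_hz))


def channel_adjacency(channels: ChannelTable, factor: float = 1.2,
                      subset: np.ndarray | None = None) -> sparse.csr_matrix:
    """Boolean adjacency from grid geometry: distance <= factor * pitch."""
    pos = channels.positions_mm()
    if subset is not None:
        pos = pos[subset]
    d = np.linalg.norm(pos[:, None] - pos[None, :], axis=2)
    adj = (d <= factor * channels.pitch_mm) & (d > 0)
    return sparse.csr_matrix(adj)


def _has_run(mask: np.ndarray, min_len: int) -> bool:
    count = 0
    for v in mask:
        count = count + 1 if v else 0
        if count >= min_len:
            return True
    return False


def _run_bounds(mask: np.ndarray, min_len: int) -> tuple[int, int] | None:
    best = None
    count = 0
    for i, v in enumerate(mask):
        count = count + 1 if v else 0
        if count >= min_len:
            start = i - count + 1
            best = (start, i) if best is None else (best[0], i)
    return best


def _extract_trials(features: FeatureMatrix, events: EventTable,
                    window_ms: tuple[float, float]) -> tuple[np.ndarray, np.ndarray]:
    """(trials, time, electrodes) array for a window around each onset."""
    rate = features.frame_rate_hz
    lo_off = int(round(window_ms[0] / 1000 * rate))
    hi_off = int(round(window_ms[1] / 1000 * rate))
    t0 = features.frame_times_s[0]
    out, kept = [], []
    for i, onset in enumerate(events.onsets_s):
        idx = int(round((onset - t0) * rate))
        if idx + lo_off < 0 or idx + hi_off > features.n_frames:
            continue
        out.append(features.data[idx + lo_off: idx + hi_off])
        kept.append(i)
    if not out:
        raise ValidationError("no trial fits the analysis window")
    return np.stack(out), np.array(kept)


# ---------------------------------------------------------------------------
# Speech-responsive electrodes
# ---------------------------------------------------------------------------

@dataclass
class ResponsiveResult:
    responsive: np.ndarray          # (E,) bool
    t_values: np.ndarray            # (T, E)
    p_values: np.ndarray
    mean_timecourse: np.ndarray     # (T, E) trial-mean HGA in the onset window


def speech_responsive(features: FeatureMatrix, events: EventTable,
                      cfg: ElectrodeStatsConfig | None = None,
                      seed: int | None = None) -> ResponsiveResult:
    cfg = cfg or ElectrodeStatsConfig()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    onset, kept = _extract_trials(features, events, cfg.onset_window_ms)
    base, _ = _extract_trials(features, EventTable(events.df.iloc[kept]),
                              cfg.baseline_window_ms)
    n = onset.shape[0]
    take = min(n, cfg.balanced_n)
    if take < cfg.balanced_n:
        logger.info("only %d trials available (< %d); using all", n, cfg.balanced_n)
    sel = rng.choice(n, size=take, replace=False)
    onset, base_mean = onset[sel], base[sel].mean(axis=1)   # (n,T,E), (n,E)

    d = onset - base_mean[:, None, :]
    m = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    ok = sd > 0
    t = np.zeros_like(m)
    t[ok] = m[ok] / (sd[ok] / np.sqrt(take))
    if not ok.all():
        logger.info("%d zero-variance time points skipped", int((~ok).sum()))
    p = np.ones_like(m)
    p[ok] = 2 * sps.t.sf(np.abs(t[ok]), take - 1)
    thresh = cfg.alpha / p.size                 # Bonferroni over E x T
    min_run = cfg.min_run_frames(features.frame_rate_hz)
    responsive = np.array([_has_run(p[:, e] < thresh, min_run)
                           for e in range(p.shape[1])])
    return ResponsiveResult(responsive, t, p, onset.mean(axis=0))


# ---------------------------------------------------------------------------
# Cluster-mass permutation machinery
# ---------------------------------------------------------------------------

def _f_oneway_stat(data: np.ndarray, groups: list[np.ndarray]) -> np.ndarray:
    """Vectorized one-way F over the trailing (T, E) axes."""
    k = len(groups)
    ns = np.array([len(g) for g in groups], dtype=float)
    N = ns.sum()
    means = np.stack([data[g].mean(axis=0) for g in groups])     # (k, T, E)
    grand = (means * ns[:, None, None]).sum(axis=0) / N
    ssb = ((means - grand) ** 2 * ns[:, None, None]).sum(axis=0)
    ssw = np.zeros_like(grand)
    for g, mg in zip(groups, means):
        ssw += ((data[g] - mg) ** 2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ssb / (k - 1)) / (ssw / (N - k))
    return np.nan_to_num(f, nan=0.0, posinf=0.0)


def _cluster_labels(mask: np.ndarray, adj_pairs: np.ndarray
                    ) -> tuple[np.ndarray, int]:
    """Connected components of suprathreshold (T, E) points.

    Adjacency: consecutive time points on the same electrode, and the same
    time point on spatially adjacent electrodes.
    """
    T, E = mask.shape
    flat = mask.ravel()
    idx_of = np.full(T * E, -1, dtype=int)
    nodes = np.flatnonzero(flat)
    if nodes.size == 0:
        return np.full(mask.shape, -1, dtype=int), 0
    idx_of[nodes] = np.arange(nodes.size)
    rows, cols = [], []
    tmask = mask[:-1] & mask[1:]
    tt, ee = np.nonzero(tmask)
    rows.append(tt * E + ee)
    cols.append((tt + 1) * E + ee)
    if adj_pairs.size:
        for a, b in adj_pairs:
            smask = mask[:, a] & mask[:, b]
            ts = np.flatnonzero(smask)
            rows.append(ts * E + a)
            cols.append(ts * E + b)
    rows = idx_of[np.concatenate(rows)] if rows else np.zeros(0, int)
    cols = idx_of[np.concatenate(cols)] if cols else np.zeros(0, int)
    g = sparse.coo_matrix((np.ones(rows.size), (rows, cols)),
                          shape=(nodes.size, nodes.size))
    n_comp, labels = connected_components(g, directed=False)
    out = np.full(T * E, -1, dtype=int)
    out[nodes] = labels
    return out.reshape(T, E), n_comp


def _max_cluster_mass(f: np.ndarray, thresh: float,
                      adj_pairs: np.ndarray) -> float:
    labels, n = _cluster_labels(f > thresh, adj_pairs)
    if n == 0:
        return 0.0
    mass = np.bincount(labels[labels >= 0].ravel(),
                       weights=f[labels >= 0].ravel(), minlength=n)
    return float(mass.max())


@dataclass
class Cluster:
    points: np.ndarray              # (n, 2) of (time, electrode)
    mass: float
    p_value: float


@dataclass
class DiscriminativeResult:
    discriminative: np.ndarray      # (E,) bool
    factor: str
    clusters: list[Cluster] = field(default_factory=list)
    f_values: np.ndarray | None = None
    p_values: np.ndarray | None = None

    def to_frame(self, frame_rate_hz: float = 400.0,
                 alpha: float = 0.05, min_run: int = 80):
        """Per-electrode summary table (flag, significant span, peak F)."""
        import pandas as pd

        rows = []
        for e in range(self.discriminative.size):
            span = None
            if self.p_values is not None:
                span = _run_bounds(self.p_values[:, e] < alpha, min_run)
            rows.append({
                "electrode": e,
                "factor": self.factor,
                "flag": bool(self.discriminative[e]),
                "first_sig_ms": None if span is None
                else span[0] / frame_rate_hz * 1000,
                "last_sig_ms": None if span is None
                else span[1] / frame_rate_hz * 1000,
                "peak_f": None if self.f_values is None
                else float(self.f_values[:, e].max()),
            })
        return pd.DataFrame(rows)


def _factor_labels(events: EventTable, factor: str,
                   inventory: SyllableInventory) -> np.ndarray:
    from .synth import manner_of, place_of

    sylls = events.df["syllable"]
    if factor == "syllable":
        vals = sylls
    elif factor == "tone":
        vals = events.df["tone"]
    elif factor == "manner":
        vals = sylls.map(manner_of)
    elif factor == "place":
        vals = sylls.map(place_of)
    else:
        raise ValueError(f"unknown factor {factor!r}")
    _, codes = np.unique(np.asarray(vals), return_inverse=True)
    return codes


def discriminative_electrodes(features: FeatureMatrix, events: EventTable,
                              factor: str, channels: ChannelTable,
                              inventory: SyllableInventory,
                              cfg: ElectrodeStatsConfig | None = None,
                              seed: int | None = None) -> DiscriminativeResult:
    """Per-electrode discriminability flags for one stimulus factor."""
    cfg = cfg or ElectrodeStatsConfig()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    data, kept = _extract_trials(features, events, cfg.onset_window_ms)
    labels = _factor_labels(EventTable(events.df.iloc[kept]), factor, inventory)
    levels, counts = np.unique(labels, return_counts=True)
    drop = levels[counts < 2]
    if drop.size:
        logger.info("excluding %d level(s) with <2 trials", drop.size)
        keep = ~np.isin(labels, drop)
        data, labels = data[keep], labels[keep]
        levels = np.unique(labels)
    min_run = cfg.min_run_frames(features.frame_rate_hz)

    if factor == "place":
        if levels.size != 2:
            raise ValidationError("place test needs exactly 2 groups")
        g0, g1 = (np.flatnonzero(labels == lv) for lv in levels)
        t, p = sps.ttest_ind(data[g0], data[g1], axis=0, equal_var=False)
        disc = np.array([_has_run(p[:, e] < cfg.alpha, min_run)
                         for e in range(p.shape[1])])
        return DiscriminativeResult(disc, factor, p_values=p)

    if factor == "tone":
        if levels.size != 4:
            raise ValidationError("tone test needs exactly 4 levels")
        take = min(cfg.balanced_n, counts.min())
        groups = [rng.choice(np.flatnonzero(labels == lv), size=take,
                             replace=False) for lv in levels]
        bal = np.concatenate(groups)
        bal_labels = np.repeat(np.arange(4), take)
        gidx = [np.flatnonzero(bal_labels == i) for i in range(4)]
        f = _f_oneway_stat(data[bal], gidx)
        dfn, dfd = 3, 4 * take - 4
        p = sps.f.sf(f, dfn, dfd)
        thresh = cfg.alpha / p.size
        disc = np.array([_has_run(p[:, e] < thresh, min_run)
                         for e in range(p.shape[1])])
        return DiscriminativeResult(disc, factor, f_values=f, p_values=p)

    # syllable / manner: cluster-mass permutation then pairwise follow-up
    if levels.size < 3:
        raise ValidationError(f"{factor} test needs >=3 levels")
    groups = [np.flatnonzero(labels == lv) for lv in levels]
    adj = channel_adjacency(channels, cfg.adjacency_factor,
                            subset=features.channel_ids)
    adj_pairs = np.column_stack(sparse.triu(adj, k=1).nonzero())
    f_obs = _f_oneway_stat(data, groups)
    obs_labels, n_clusters = _cluster_labels(f_obs > cfg.cluster_f_threshold,
                                             adj_pairs)
    null = np.empty(cfg.n_permutations)
    for i in range(cfg.n_permutations):
        perm = rng.permutation(labels)
        pgroups = [np.flatnonzero(perm == lv) for lv in levels]
        null[i] = _max_cluster_mass(_f_oneway_stat(data, pgroups),
                                    cfg.cluster_f_threshold, adj_pairs)

    clusters = []
    surviving = np.zeros(f_obs.shape, dtype=bool)
    for c in range(n_clusters):
        pts = np.column_stack(np.nonzero(obs_labels == c))
        mass = float(f_obs[obs_labels == c].sum())
        p_c = (1 + (null >= mass).sum()) / (cfg.n_permutations + 1)
        clusters.append(Cluster(pts, mass, p_c))
        if p_c < cfg.alpha:
            surviving[obs_labels == c] = True

    disc = np.zeros(f_obs.shape[1], dtype=bool)
    if surviving.any():
        disc = _pairwise_level_runs(data, labels, levels, surviving, cfg,
                                    min_run)
    return DiscriminativeResult(disc, factor, clusters, f_values=f_obs)


def _pairwise_level_runs(data, labels, levels, surviving, cfg, min_run):
    """Welch pairwise tests inside surviving clusters; >=min_levels rule."""
    T, E = surviving.shape
    pair_p = []
    pairs = [(i, j) for i in range(levels.size) for j in range(i + 1, levels.size)]
    for i, j in pairs:
        a = data[labels == levels[i]]
        b = data[labels == levels[j]]
        _, p = sps.ttest_ind(a, b, axis=0, equal_var=False)
        pair_p.append(p)
    pair_p = np.stack(pair_p)                           # (n_pairs, T, E)
    sel = np.broadcast_to(surviving, pair_p.shape)
    flat = pair_p[sel]
    method = "fdr_bh" if cfg.correction == "fdr" else "bonferroni"
    sig_flat = multipletests(flat, alpha=cfg.alpha, method=method)[0] \
        if flat.size else np.zeros(0, bool)
    sig = np.zeros(pair_p.shape, dtype=bool)
    sig[sel] = sig_flat
    disc = np.zeros(E, dtype=bool)
    for e in range(E):
        n_lv = np.zeros(T, dtype=int)
        for t in range(T):
            lv = set()
            for (i, j), s in zip(pairs, sig[:, t, e]):
                if s:
                    lv.update((i, j))
            n_lv[t] = len(lv)
        disc[e] = _has_run(n_lv >= cfg.min_levels, min_run)
    return disc


# ---------------------------------------------------------------------------
# Gradient saliency
# ---------------------------------------------------------------------------

@dataclass
class SaliencyResult:
    scores: np.ndarray              # (E,) in [0, 1], max 1
    order: np.ndarray               # electrodes, descending contribution
    mask90: np.ndarray              # shortest prefix reaching 90% cumulative


def cumulative_mask(scores: np.ndarray, frac: float = 0.9) -> np.ndarray:
    order = np.argsort(-scores, kind="stable")
    csum = np.cumsum(scores[order])
    n_sel = int(np.searchsorted(csum, frac * csum[-1])) + 1
    mask = np.zeros(scores.size, dtype=bool)
    mask[order[:n_sel]] = True
    return mask


def gradient_saliency(model: DecoderModel,
                      segments: list[TrialSegment]) -> SaliencyResult:
    """Input-gradient electrode contributions of a trained decoder.

    Backpropagates the cross-entropy loss w.r.t. the true labels to the input
    features; per trial the absolute gradient is summed over time, then
    averaged over trials and normalized so the top electrode scores 1.
    """
    if not segments:
        raise ValidationError("need at least one segment")
    X, y = segments_to_arrays(segments, model.stream)
    Y = one_hot(y, model.net.n_classes)
    probs, caches = model.net.forward(X, train=False)
    _, dprobs = nn.cross_entropy(probs, Y)
    dx = model.net.backward(dprobs * X.shape[0], caches)   # per-trial scale
    per_trial = np.abs(dx).sum(axis=1)                     # (B, E)
    scores = per_trial.mean(axis=0)
    scores = scores / scores.max()
    order = np.argsort(-scores, kind="stable")
    return SaliencyResult(scores, order, cumulative_mask(scores))
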