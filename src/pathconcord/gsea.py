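"""Gene set enrichment analysis with a gene-set permutation null.

The statistic is the weighted Kolmogorov–Smirnov running sum of Subramanian
et al.: genes are ranked by a two-class signal-to-noise metric, and for each
gene set the running sum gains ``|r_j|^p / N_R`` at member genes (N_R is the
sum of ``|r_j|^p`` over members) and loses ``1/(N - N_H)`` at non-members.
The enrichment score (ES) is the signed extreme of that walk. Significance
comes from a gene-set permutation null: random same-size gene sets drawn from
the ranked universe. Each ES is normalised by the mean magnitude of
same-signed null scores (NES), and the false discovery rate q compares the
pooled normalised null to the observed NES distribution, separately per sign.

Defaults follow the standard microarray protocol: 1,000 permutations,
weight exponent p = 1 ("weighted"), gene-set size bounds 15–500, and the
signal-to-noise ranking metric with its conventional standard-deviation
floors.

The null is *gene-set* permutation (random sets from the universe), not
phenotype permutation; the two give different nulls and the latter is out of
scope here.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import ExpressionDataset, GeneSetCollection

logger = logging.getLogger("pathconcord")

__all__ = [
    "GseaParams",
    "RankedList",
    "signal_to_noise",
    "enrichment_score",
    "permutation_null",
    "normalize_and_test",
    "fdr_q",
    "run_gsea",
    "RESULT_COLUMNS",
]

RESULT_COLUMNS = ["set", "size", "es", "nes", "p_nominal", "q_fdr",
                  "leading_edge", "status"]

#: status values an EnrichmentResult row can carry
STATUS_TESTED = "tested"
STATUS_TOO_SMALL = "too_small"
STATUS_TOO_LARGE = "too_large"
STATUS_NOT_TESTABLE = "not_testable"


@dataclass(frozen=True)
class GseaParams:
    """Run parameters.

    n_perm: gene-set permutations per set (default 1,000).
    weight_exponent: p in |r|^p hit weighting; 1.0 = "weighted".
    min_size / max_size: bounds on the number of *detectable* member genes.
    rng_seed: master seed; each set gets an independent substream derived
        from the seed and the set name, so results do not depend on the
        order sets are listed in.
    """

    n_perm: int = 1000
    weight_exponent: float = 1.0
    min_size: int = 15
    max_size: int = 500
    metric: str = "signal_to_noise"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if self.weight_exponent < 0:
            raise ValueError("weight_exponent must be >= 0")
        if not (1 <= self.min_size <= self.max_size):
            raise ValueError("need 1 <= min_size <= max_size")
        if self.metric != "signal_to_noise":
            raise ValueError(f"unsupported metric {self.metric!r}")


@dataclass
class RankedList:
    """Genes in descending metric order with their scores."""

    genes: np.ndarray   # dtype object/str, unique
    scores: np.ndarray  # float, non-increasing

    def __post_init__(self) -> None:
        self.genes = np.asarray(self.genes)
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.genes) != len(self.scores):
            raise ValueError("genes and scores length mismatch")
        if len(np.unique(self.genes)) != len(self.genes):
            raise ValueError("ranked genes must be unique")
        if np.any(np.diff(self.scores) > 1e-12):
            raise ValueError("scores must be non-increasing")

    def __len__(self) -> int:
        return len(self.genes)

    @property
    def index(self) -> dict[str, int]:
        """Gene -> rank position (cached)."""
        if not hasattr(self, "_index"):
            self._index = {g: i for i, g in enumerate(self.genes)}
        return self._index


# ---------------------------------------------------------------------------
# ranking metric

def signal_to_noise(data: ExpressionDataset) -> RankedList:
    """Rank genes by the two-class signal-to-noise ratio.

    s = (mean_case - mean_control) / (sd_case + sd_control) with sample
    (n-1) standard deviations, each floored at max(0.2*|class mean|, 0.2).
    The floor keeps low-variance genes from dominating and guarantees a
    positive denominator. Ties are broken by ascending gene symbol so runs
    are platform-independent.
    """
    case = data.values[data.case_samples].to_numpy(float)
    ctrl = data.values[data.control_samples].to_numpy(float)
    if case.shape[1] < 2 or ctrl.shape[1] < 2:
        raise ValueError("signal-to-noise needs >= 2 samples per class")
    mu_c, mu_k = case.mean(axis=1), ctrl.mean(axis=1)
    sd_c = case.std(axis=1, ddof=1)
    sd_k = ctrl.std(axis=1, ddof=1)
    sd_c = np.maximum(sd_c, np.maximum(0.2 * np.abs(mu_c), 0.2))
    sd_k = np.maximum(sd_k, np.maximum(0.2 * np.abs(mu_k), 0.2))
    s = (mu_c - mu_k) / (sd_c + sd_k)
    genes = data.values.index.to_numpy()
    order = np.lexsort((genes, -s))
    return RankedList(genes=genes[order], scores=s[order])


# ---------------------------------------------------------------------------
# running-sum statistic

def _hit_weights(abs_scores_p: np.ndarray, hit_idx: np.ndarray) -> np.ndarray:
    """Normalised hit increments; uniform fallback when all hit scores are 0."""
    w = abs_scores_p[hit_idx]
    n_r = w.sum()
    if n_r == 0:
        return np.full(len(hit_idx), 1.0 / len(hit_idx))
    return w / n_r


def enrichment_score(ranked: RankedList, members, p: float = 1.0):
    """Walk the ranked list and return ``(ES, running profile, leading_edge)``.

    ES is the extreme of the running sum with the largest absolute value
    (sign kept; an exact +/- tie resolves to the positive extreme). The
    leading edge contains the member genes at or before the extreme for
    ES > 0 and at or after it for ES < 0 (empty when ES == 0). For every
    proper subset the walk ends exactly at zero, which is asserted.
    """
    n = len(ranked)
    idx_map = ranked.index
    hit_idx = np.array(sorted(idx_map[g] for g in members if g in idx_map),
                       dtype=int)
    n_h = len(hit_idx)
    if n_h == 0:
        raise ValueError("no member gene present in the ranked list")
    if n_h >= n:
        # every gene is a hit: the walk climbs monotonically to 1
        running = np.cumsum(_hit_weights(np.abs(ranked.scores) ** p,
                                         np.arange(n)))
        return 1.0, running, list(ranked.genes)

    steps = np.full(n, -1.0 / (n - n_h))
    steps[hit_idx] = _hit_weights(np.abs(ranked.scores) ** p, hit_idx)
    running = np.cumsum(steps)
    assert abs(running[-1]) < 1e-9, "running sum must end at 0"
    i_max = int(np.argmax(running))
    i_min = int(np.argmin(running))
    if running[i_max] >= -running[i_min]:
        es = float(running[i_max])
        leading = [ranked.genes[i] for i in hit_idx if i <= i_max]
    else:
        es = float(running[i_min])
        leading = [ranked.genes[i] for i in hit_idx if i >= i_min]
    if es == 0.0:
        leading = []
    return es, running, leading


def _batch_es(abs_scores_p: np.ndarray, idx: np.ndarray, n: int) -> np.ndarray:
    """Vectorised ES for many same-size index sets.

    ``idx`` is (B, m), each row sorted ascending, entries in [0, n). Exploits
    that between hits the walk is linear: maxima sit immediately after a hit
    and minima immediately before one (or at the final zero).
    """
    b, m = idx.shape
    if m >= n:
        return np.ones(b)
    w = abs_scores_p[idx]                          # (B, m)
    n_r = w.sum(axis=1, keepdims=True)
    frac = np.divide(w, n_r, out=np.full_like(w, 1.0 / m), where=n_r > 0)
    cum = np.cumsum(frac, axis=1)
    dm = 1.0 / (n - m)
    misses_before = idx - np.arange(m)             # misses strictly before hit k
    after = cum - misses_before * dm               # value just after hit k
    before = after - frac                          # value just before hit k
    mx = after.max(axis=1)
    mn = np.minimum(before.min(axis=1), 0.0)       # final value 0 is attained
    return np.where(mx >= -mn, mx, mn)


def permutation_null(ranked: RankedList, n_h: int, params: GseaParams,
                     rng: np.random.Generator | None = None) -> np.ndarray:
    """Null ES sample: ``n_perm`` random same-size gene sets from the universe.

    Each draw takes ``n_h`` genes uniformly without replacement from the
    ranked universe and records its ES. Reproducible given the seed.
    """
    n = len(ranked)
    if not (1 <= n_h < n):
        raise ValueError(f"need 1 <= n_h < N, got n_h={n_h}, N={n}")
    if rng is None:
        rng = np.random.default_rng(params.rng_seed)
    abs_p = np.abs(ranked.scores) ** params.weight_exponent
    # batched sampling without replacement: the n_h smallest of n uniform
    # keys per row are a uniform subset; chunked to bound memory
    out = np.empty(params.n_perm, dtype=float)
    chunk = max(1, min(params.n_perm, 4_000_000 // n))
    for start in range(0, params.n_perm, chunk):
        b = min(chunk, params.n_perm - start)
        keys = rng.random((b, n))
        draws = np.argpartition(keys, n_h, axis=1)[:, :n_h]
        draws.sort(axis=1)
        out[start:start + b] = _batch_es(abs_p, draws, n)
    return out


def normalize_and_test(es: float, null_es: np.ndarray):
    """Normalise an ES against its permutation null.

    NES = ES / mean(|null ES of the same sign|); the nominal p is the
    fraction of same-signed null scores at least as extreme, with the
    (k+1)/(n+1) guard so p > 0. Returns ``(nes, p)``, or ``(None, None)``
    when no same-signed null value exists (caller degrades the set to
    not-testable). ES == 0 maps to NES 0, p 1 (no direction).
    """
    null_es = np.asarray(null_es, dtype=float)
    if null_es.size == 0:
        raise ValueError("empty permutation null")
    if es == 0.0:
        return 0.0, 1.0
    if es > 0:
        same = null_es[null_es > 0]
        if same.size == 0:
            return None, None
        nes = es / same.mean()
        p = (np.count_nonzero(same >= es) + 1) / (same.size + 1)
    else:
        same = null_es[null_es < 0]
        if same.size == 0:
            return None, None
        nes = es / np.abs(same).mean()
        p = (np.count_nonzero(same <= es) + 1) / (same.size + 1)
    return float(nes), float(p)


def _normalize_null(null_es: np.ndarray) -> np.ndarray:
    """Per-set normalisation of a null ES sample into null NES values.

    Positive scores divide by the mean positive score, negative by the mean
    magnitude of negative scores; exact zeros stay zero (they belong to
    neither direction).
    """
    out = np.zeros_like(null_es, dtype=float)
    pos = null_es > 0
    neg = null_es < 0
    if pos.any():
        out[pos] = null_es[pos] / null_es[pos].mean()
    if neg.any():
        out[neg] = null_es[neg] / np.abs(null_es[neg]).mean()
    return out


def fdr_q(observed_nes: np.ndarray, null_nes_pool: np.ndarray) -> np.ndarray:
    """Permutation FDR q per tested set.

    For a set with NES* > 0,
    q = [fraction of positive pooled null NES >= NES*]
      / [fraction of positive observed NES >= NES*], clipped to [0, 1];
    mirrored with <= for NES* < 0. Each direction uses only same-signed
    values in both numerator and denominator; the denominator counts the set
    itself, so it is never zero. NES == 0 gets q = 1.
    """
    observed_nes = np.asarray(observed_nes, dtype=float)
    null_nes_pool = np.asarray(null_nes_pool, dtype=float)
    obs_pos = observed_nes[observed_nes > 0]
    obs_neg = observed_nes[observed_nes < 0]
    null_pos = null_nes_pool[null_nes_pool > 0]
    null_neg = null_nes_pool[null_nes_pool < 0]
    q = np.empty_like(observed_nes)
    for i, nes in enumerate(observed_nes):
        if nes > 0:
            num = np.count_nonzero(null_pos >= nes) / null_pos.size \
                if null_pos.size else 0.0
            den = np.count_nonzero(obs_pos >= nes) / obs_pos.size
        elif nes < 0:
            num = np.count_nonzero(null_neg <= nes) / null_neg.size \
                if null_neg.size else 0.0
            den = np.count_nonzero(obs_neg <= nes) / obs_neg.size
        else:
            q[i] = 1.0
            continue
        q[i] = min(1.0, num / den)
    return q


def _set_rng(seed: int, name: str) -> np.random.Generator:
    """Independent substream per gene set, stable under collection order."""
    return np.random.default_rng(
        np.random.SeedSequence([seed & 0x7FFFFFFF, zlib.crc32(name.encode())]))


def run_gsea(data: ExpressionDataset, sets: GeneSetCollection,
             params: GseaParams | None = None) -> pd.DataFrame:
    """Full GSEA over a collection; one row per set.

    Each set is restricted to genes present in the data. Sets whose
    detectable size falls below ``min_size`` (status ``too_small``) or above
    ``max_size`` (``too_large``) are excluded from testing and from the FDR
    pooling. Remaining sets are scored, normalised and FDR'd; the table is
    sorted by NES descending (untested sets last). Deterministic given
    (data, sets, params).
    """
    if params is None:
        params = GseaParams()
    ranked = signal_to_noise(data)
    universe = set(ranked.genes)
    n = len(ranked)

    rows: list[dict] = []
    tested: list[dict] = []
    null_nes_pool: list[np.ndarray] = []
    for name in sets.names:
        detectable = [g for g in sets.members(name) if g in universe]
        n_h = len(detectable)
        if n_h < params.min_size:
            rows.append(dict(set=name, size=n_h, status=STATUS_TOO_SMALL))
            continue
        if n_h > params.max_size or n_h >= n:
            rows.append(dict(set=name, size=n_h, status=STATUS_TOO_LARGE))
            continue
        es, _, leading = enrichment_score(ranked, detectable,
                                          p=params.weight_exponent)
        null = permutation_null(ranked, n_h, params,
                                rng=_set_rng(params.rng_seed, name))
        nes, p_nom = normalize_and_test(es, null)
        if nes is None:
            logger.warning("set %s: no same-signed null scores; not testable",
                           name)
            rows.append(dict(set=name, size=n_h, es=es,
                             status=STATUS_NOT_TESTABLE))
            continue
        tested.append(dict(set=name, size=n_h, es=es, nes=nes,
                           p_nominal=p_nom,
                           leading_edge=",".join(map(str, leading)),
                           status=STATUS_TESTED))
        null_nes_pool.append(_normalize_null(null))

    if not tested:
        logger.warning("run_gsea: zero testable sets")
    else:
        nes_vec = np.array([t["nes"] for t in tested])
        qs = fdr_q(nes_vec, np.concatenate(null_nes_pool))
        for t, q in zip(tested, qs):
            t["q_fdr"] = float(q)
    table = pd.DataFrame(tested + rows)
    for col in RESULT_COLUMNS:
        if col not in table.columns:
            table[col] = np.nan if col not in ("set", "status", "leading_edge") else ""
    table = table[RESULT_COLUMNS]
    table = table.sort_values(["nes", "set"], ascending=[False, True],
                              na_position="last", kind="mergesort")
    return table.reset_index(drop=True)
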