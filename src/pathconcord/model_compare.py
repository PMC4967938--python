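"""Pairwise concordance of pathway-regulation profiles between models.

Whether one model's pathway regulation predicts another's is measured by
predictive values: PPV = |Up1 ∩ Up2| / |Up2| (the fraction of pathways
upregulated in model 2 that are also up in model 1) and NPV analogously for
downregulated pathways. The chance baseline is the base rate of calls in
model 1 — if 10% of pathways are up in model 1, an independent model 2 would
yield PPV 10% — and the gain over that baseline is reported in percentage
points. Statistical dependence of the two three-state profiles is tested
with a Pearson chi-squared test on the 3×3 up/down/null contingency table
(P <= 0.05 counts a pair as significantly concordant; no multiple-testing
correction is applied across pairs).

Also here: the shared-regulation NES matrix for a subgroup of models and the
tally of genes recurring in leading edges across datasets (core genes).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .gsea import STATUS_TESTED
from .pathway_state import STATES, PathwayStateProfile

logger = logging.getLogger("pathconcord")

__all__ = [
    "ComparisonResult",
    "predictive_values",
    "chance_expectation",
    "delta_over_chance",
    "contingency_table",
    "chi_squared_test",
    "compare_pair",
    "compare_all",
    "shared_regulation",
    "consistent_core_genes",
    "PAIR_COLUMNS",
]

PAIR_COLUMNS = ["model1", "model2", "species_pair", "ppv_12", "npv_12",
                "ppv_21", "npv_21", "mean_pv", "e_ppv_1", "e_npv_1",
                "e_ppv_2", "e_npv_2", "delta_points", "chi2_stat", "chi2_df",
                "chi2_p", "significant"]


@dataclass
class ComparisonResult:
    """Concordance statistics for one ordered-convention pair (1, 2).

    Predictive values carry a direction: ``ppv_12`` asks how well model 2's
    upregulated pathways predict model 1 (denominator |Up2|); ``ppv_21`` is
    the reverse. ``mean_pv`` and ``delta_points`` average the defined values
    of both directions; the chi-squared test is direction-symmetric.
    """

    model1: str
    model2: str
    ppv_12: float  # NaN when undefined (|Up2| = 0)
    npv_12: float
    ppv_21: float
    npv_21: float
    mean_pv: float
    e_ppv_1: float
    e_npv_1: float
    e_ppv_2: float
    e_npv_2: float
    delta_points: float
    table: np.ndarray
    chi2_stat: float
    chi2_df: int
    chi2_p: float

    @property
    def significant(self) -> bool:
        return self.chi2_p <= 0.05


def _check_same_collection(p1: PathwayStateProfile, p2: PathwayStateProfile):
    if not p1.pathways.equals(p2.pathways):
        raise ValueError("profiles cover different pathway collections")


def predictive_values(profile1: PathwayStateProfile,
                      profile2: PathwayStateProfile):
    """``(PPV, NPV, mean_pv)`` of predicting model 1 from model 2.

    PPV = |Up1 ∩ Up2| / |Up2|, NPV = |Down1 ∩ Down2| / |Down2|. A zero
    denominator leaves that value undefined (NaN, excluded from the mean and
    logged); with both undefined the mean is NaN too and the pair is
    excluded from summaries by the caller.
    """
    _check_same_collection(profile1, profile2)
    up1, up2 = profile1.up_set(), profile2.up_set()
    dn1, dn2 = profile1.down_set(), profile2.down_set()
    ppv = len(up1 & up2) / len(up2) if up2 else math.nan
    npv = len(dn1 & dn2) / len(dn2) if dn2 else math.nan
    if not up2:
        logger.info("PPV undefined for (%s, %s): no up calls in %s",
                    profile1.dataset_id, profile2.dataset_id,
                    profile2.dataset_id)
    if not dn2:
        logger.info("NPV undefined for (%s, %s): no down calls in %s",
                    profile1.dataset_id, profile2.dataset_id,
                    profile2.dataset_id)
    defined = [v for v in (ppv, npv) if not math.isnan(v)]
    mean_pv = float(np.mean(defined)) if defined else math.nan
    return ppv, npv, mean_pv


def chance_expectation(profile1: PathwayStateProfile):
    """Expected ``(PPV, NPV)`` under independence: model 1's call base rates.

    E_PPV = |Up1| / N and E_NPV = |Down1| / N over the N pathways of the
    collection — the value a shuffled partner profile would achieve on
    average.
    """
    n = len(profile1.pathways)
    return len(profile1.up_set()) / n, len(profile1.down_set()) / n


def delta_over_chance(pv, chance) -> float:
    """Mean gain of (PPV, NPV) over (E_PPV, E_NPV), in percentage points.

    Undefined sides (NaN predictive value) are skipped; NaN when both are.
    """
    diffs = [100.0 * (v - e) for v, e in zip(pv, chance) if not math.isnan(v)]
    return float(np.mean(diffs)) if diffs else math.nan


def contingency_table(profile1: PathwayStateProfile,
                      profile2: PathwayStateProfile) -> np.ndarray:
    """3×3 counts: rows = model-1 state, columns = model-2 state (up/down/null)."""
    _check_same_collection(profile1, profile2)
    table = np.zeros((3, 3), dtype=int)
    idx = {s: i for i, s in enumerate(STATES)}
    for s1, s2 in zip(profile1.states.values, profile2.states.values):
        table[idx[s1], idx[s2]] += 1
    return table


def chi_squared_test(table: np.ndarray):
    """Pearson chi-squared (no continuity correction) on a contingency table.

    Rows and columns with a zero margin are dropped and the degrees of
    freedom adjusted accordingly (logged). A table that degenerates to a
    single row or column (e.g. all counts in one cell) has no independence
    structure to test: statistic 0, df 0, p = 1, with a warning.
    """
    table = np.asarray(table)
    if table.sum() <= 0:
        raise ValueError("contingency table has zero total count")
    reduced = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
    if reduced.shape != table.shape:
        logger.info("chi_squared_test: dropped zero-margin rows/cols "
                    "%s -> %s", table.shape, reduced.shape)
    if min(reduced.shape) < 2:
        logger.warning("chi_squared_test: degenerate table; reporting p = 1")
        return 0.0, 0, 1.0
    res = stats.chi2_contingency(reduced, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def compare_pair(profile1: PathwayStateProfile,
                 profile2: PathwayStateProfile) -> ComparisonResult:
    """All concordance statistics for one pair, both directions."""
    ppv_12, npv_12, mean_12 = predictive_values(profile1, profile2)
    ppv_21, npv_21, mean_21 = predictive_values(profile2, profile1)
    e1 = chance_expectation(profile1)
    e2 = chance_expectation(profile2)
    delta_12 = delta_over_chance((ppv_12, npv_12), e1)
    delta_21 = delta_over_chance((ppv_21, npv_21), e2)
    pvs = [v for v in (ppv_12, npv_12, ppv_21, npv_21) if not math.isnan(v)]
    mean_pv = float(np.mean(pvs)) if pvs else math.nan
    deltas = [d for d in (delta_12, delta_21) if not math.isnan(d)]
    delta = float(np.mean(deltas)) if deltas else math.nan
    table = contingency_table(profile1, profile2)
    stat, df, p = chi_squared_test(table)
    return ComparisonResult(
        model1=profile1.dataset_id, model2=profile2.dataset_id,
        ppv_12=ppv_12, npv_12=npv_12, ppv_21=ppv_21, npv_21=npv_21,
        mean_pv=mean_pv, e_ppv_1=e1[0], e_npv_1=e1[1],
        e_ppv_2=e2[0], e_npv_2=e2[1], delta_points=delta,
        table=table, chi2_stat=stat, chi2_df=df, chi2_p=p)


def compare_all(profiles: list[PathwayStateProfile],
                species: dict[str, str]):
    """All unordered pairs of profiles plus species-group summaries.

    ``species`` maps dataset id -> ``"human"`` or ``"mouse"``. Returns
    ``(pair_table, group_summary, partner_counts)``:

    * ``pair_table`` — one row per unordered pair (canonical id order) with
      both directions' predictive values, the direction-averaged ``mean_pv``
      and ``delta_points``, and the (direction-symmetric) chi-squared test.
    * ``group_summary`` — per species pair (human-human, mouse-mouse,
      human-mouse): mean of ``mean_pv`` and ``delta_points`` and the percent
      of significant pairs.
    * ``partner_counts`` — per dataset, the number of partners with a
      significant chi-squared test.
    """
    if len(profiles) < 2:
        raise ValueError("need >= 2 profiles")
    profiles = sorted(profiles, key=lambda p: p.dataset_id)
    unknown = {p.dataset_id for p in profiles} - set(species)
    if unknown:
        raise ValueError(f"datasets without species label: {sorted(unknown)}")
    rows = []
    partner_counts = {p.dataset_id: 0 for p in profiles}
    for p1, p2 in itertools.combinations(profiles, 2):
        res = compare_pair(p1, p2)
        pair_species = "-".join(sorted([species[p1.dataset_id],
                                        species[p2.dataset_id]]))
        rows.append(dict(model1=res.model1, model2=res.model2,
                         species_pair=pair_species,
                         ppv_12=res.ppv_12, npv_12=res.npv_12,
                         ppv_21=res.ppv_21, npv_21=res.npv_21,
                         mean_pv=res.mean_pv,
                         e_ppv_1=res.e_ppv_1, e_npv_1=res.e_npv_1,
                         e_ppv_2=res.e_ppv_2, e_npv_2=res.e_npv_2,
                         delta_points=res.delta_points,
                         chi2_stat=res.chi2_stat, chi2_df=res.chi2_df,
                         chi2_p=res.chi2_p, significant=res.significant))
        if res.significant:
            partner_counts[res.model1] += 1
            partner_counts[res.model2] += 1
    pair_table = pd.DataFrame(rows, columns=PAIR_COLUMNS)
    summaries = []
    for name, grp in pair_table.groupby("species_pair"):
        summaries.append(dict(
            species_pair=name,
            n_pairs=len(grp),
            mean_pv=float(grp["mean_pv"].mean()),
            mean_delta_points=float(grp["delta_points"].mean()),
            pct_significant=100.0 * float(grp["significant"].mean()),
        ))
    group_summary = pd.DataFrame(summaries)
    counts = pd.DataFrame({"dataset": list(partner_counts),
                           "n_significant_partners":
                               list(partner_counts.values())})
    return pair_table, group_summary, counts


def shared_regulation(profiles: list[PathwayStateProfile],
                      fdr_threshold: float = 0.25):
    """Subgroup NES matrix masked by significance, plus shared pathways.

    Returns ``(matrix, shared)``: a pathways × datasets DataFrame of NES
    where q <= threshold (NaN where the pathway is null — not significant or
    not detectable), and the list of pathways significantly regulated in
    *every* subgroup member with a consistent sign.
    """
    if not profiles:
        raise ValueError("empty subgroup")
    pathways = profiles[0].pathways
    cols = {}
    for prof in profiles:
        if not prof.pathways.equals(pathways):
            raise ValueError("profiles cover different pathway collections")
        sig = (prof.q <= fdr_threshold) & prof.nes.notna()
        cols[prof.dataset_id] = prof.nes.where(sig)
    matrix = pd.DataFrame(cols, index=pathways)
    shared = []
    for pw in pathways:
        vals = matrix.loc[pw]
        if vals.notna().all() and (np.all(vals > 0) or np.all(vals < 0)):
            shared.append(pw)
    return matrix, shared


def consistent_core_genes(results: dict[str, pd.DataFrame], pathway: str,
                          k_min: int, fdr_threshold: float = 0.25) -> pd.DataFrame:
    """Genes recurring in the pathway's leading edge across upregulated datasets.

    ``results`` maps dataset id -> ``run_gsea`` table. Among the datasets
    where the pathway is called up (tested, NES > 0, q <= threshold), each
    gene's leading-edge memberships are tallied; genes with tally >= k_min
    are returned sorted by descending tally then symbol. Requires the
    pathway to have been tested in at least ``k_min`` datasets.
    """
    tally: dict[str, int] = {}
    n_tested = 0
    for dsid, table in results.items():
        row = table[table["set"] == pathway]
        if row.empty:
            continue
        row = row.iloc[0]
        if row["status"] != STATUS_TESTED:
            continue
        n_tested += 1
        if row["nes"] > 0 and row["q_fdr"] <= fdr_threshold:
            genes = [g for g in str(row["leading_edge"]).split(",") if g]
            for g in genes:
                tally[g] = tally.get(g, 0) + 1
    if n_tested < k_min:
        raise ValueError(
            f"pathway {pathway!r} tested in only {n_tested} datasets; "
            f"need >= {k_min}")
    items = sorted(((g, c) for g, c in tally.items() if c >= k_min),
                   key=lambda gc: (-gc[1], gc[0]))
    return pd.DataFrame(items, columns=["gene", "n_leading_edges"])
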