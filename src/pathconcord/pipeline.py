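"""End-to-end orchestration: GSEA per dataset -> profiles -> comparisons.

Runs the full concordance analysis over a list of labelled datasets: per-
dataset enrichment with a shared parameter set (each dataset gets an
independent RNG substream derived from the master seed and its id, so adding
or reordering datasets never perturbs the others' results), three-state
classification, all-pairs predictive-value comparison, species-group
statistics and, for a configured subgroup, the shared-regulation NES matrix.
All tables are canonicalised by dataset id, making output independent of
manifest order.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import replace

import pandas as pd

from . import __version__ as _pkg_version
from .cohort_stats import kruskal_wallis_dunn, proportions_test
from .gsea import GseaParams, run_gsea
from .io_formats import ExpressionDataset, GeneSetCollection, write_results
from .model_compare import compare_all, shared_regulation
from .pathway_state import classify

logger = logging.getLogger("pathconcord")

__all__ = ["run_pipeline"]


def _dataset_params(params: GseaParams, dataset_id: str) -> GseaParams:
    sub = (params.rng_seed & 0x7FFFFFFF) ^ zlib.crc32(dataset_id.encode())
    return replace(params, rng_seed=int(sub) & 0x7FFFFFFF)


def run_pipeline(datasets: list[tuple[ExpressionDataset, str]],
                 collection: GeneSetCollection,
                 params: GseaParams | None = None,
                 fdr_threshold: float = 0.25,
                 subgroup: list[str] | None = None,
                 out_dir: str | None = None) -> dict:
    """Run the whole analysis; returns (and optionally writes) all tables.

    ``datasets`` pairs each :class:`ExpressionDataset` with its species
    label (``"human"``/``"mouse"``). Returns a dict with keys
    ``enrichment``, ``profiles``, ``pairs``, ``group_summary``,
    ``partner_counts``, ``species_tests`` and, when ``subgroup`` names >= 1
    dataset ids, ``shared_matrix``/``shared_pathways``. With ``out_dir`` the
    tables are written as TSV plus a JSON run summary.
    """
    if len(datasets) < 2:
        raise ValueError("need >= 2 datasets")
    ids = [ds.dataset_id for ds, _ in datasets]
    if len(set(ids)) != len(ids):
        raise ValueError("dataset ids must be unique")
    if params is None:
        params = GseaParams()
    datasets = sorted(datasets, key=lambda pair: pair[0].dataset_id)
    species = {ds.dataset_id: sp for ds, sp in datasets}

    results = {}
    profiles = []
    enrich_frames = []
    for ds, _ in datasets:
        try:
            table = run_gsea(ds, collection, _dataset_params(params, ds.dataset_id))
        except Exception:
            logger.error("pipeline failed at dataset %s", ds.dataset_id)
            raise
        results[ds.dataset_id] = table
        profiles.append(classify(table, collection, fdr_threshold,
                                 dataset_id=ds.dataset_id))
        enriched = table.copy()
        enriched.insert(0, "dataset", ds.dataset_id)
        enrich_frames.append(enriched)

    pair_table, group_summary, partner_counts = compare_all(
        profiles, species)

    species_tests = _species_tests(pair_table, partner_counts, species)

    profile_frames = []
    for prof in profiles:
        frame = prof.to_frame()
        frame.insert(0, "dataset", prof.dataset_id)
        profile_frames.append(frame)

    out = {
        "enrichment": pd.concat(enrich_frames, ignore_index=True),
        "profiles": pd.concat(profile_frames, ignore_index=True),
        "pairs": pair_table,
        "group_summary": group_summary,
        "partner_counts": partner_counts,
        "species_tests": species_tests,
        "results_by_dataset": results,
        "profile_objects": profiles,
    }
    if subgroup:
        chosen = [p for p in profiles if p.dataset_id in set(subgroup)]
        missing = set(subgroup) - {p.dataset_id for p in chosen}
        if missing:
            raise ValueError(f"subgroup ids not in manifest: {sorted(missing)}")
        matrix, shared = shared_regulation(chosen, fdr_threshold)
        out["shared_matrix"] = matrix
        out["shared_pathways"] = shared

    if out_dir is not None:
        tables = {k: out[k] for k in ("enrichment", "profiles", "pairs",
                                      "group_summary", "partner_counts",
                                      "species_tests")}
        if "shared_matrix" in out:
            tables["shared_matrix"] = out["shared_matrix"].reset_index()
            tables["shared_pathways"] = pd.DataFrame(
                {"pathway": out["shared_pathways"]})
        summary = dict(
            version=_pkg_version,
            n_datasets=len(datasets),
            dataset_ids=[ds.dataset_id for ds, _ in datasets],
            species=species,
            n_pathways=len(collection),
            params=dict(n_perm=params.n_perm,
                        weight_exponent=params.weight_exponent,
                        min_size=params.min_size, max_size=params.max_size,
                        metric=params.metric, rng_seed=params.rng_seed),
            fdr_threshold=fdr_threshold,
            subgroup=subgroup or [],
            caveat=("pairwise values sharing a dataset are not independent; "
                    "species-group tests ignore this, as is conventional"),
        )
        write_results(tables, out_dir, summary=summary)
    return out


def _species_tests(pair_table: pd.DataFrame, partner_counts: pd.DataFrame,
                   species: dict[str, str]) -> pd.DataFrame:
    """Species-effect tests over the pair matrix, where group sizes allow.

    Kruskal-Wallis + Dunn on the per-pair mean predictive values across the
    species-pair groups, and equality-of-proportions tests (with continuity
    correction) on significant-pair counts, computed both on pair counts per
    group and on per-dataset significant-partner counts (the source text is
    ambiguous about which was used; both are reported, labelled).
    """
    rows = []
    grouped = pair_table.dropna(subset=["mean_pv"])
    sizes = grouped.groupby("species_pair").size()
    if (sizes >= 2).sum() >= 2:
        usable = grouped[grouped["species_pair"].isin(
            sizes.index[sizes >= 2])]
        kw = kruskal_wallis_dunn(usable["mean_pv"].to_numpy(),
                                 usable["species_pair"].to_numpy())
        rows.append(dict(test="kruskal_wallis", group1="all", group2="all",
                         statistic=kw.h_stat, df=kw.h_df, p=kw.h_p))
        for r in kw.dunn.itertuples(index=False):
            rows.append(dict(test="dunn_bonferroni", group1=r.group1,
                             group2=r.group2, statistic=r.z, df=float("nan"),
                             p=r.p_bonferroni))
    hh = pair_table[pair_table["species_pair"] == "human-human"]
    mm = pair_table[pair_table["species_pair"] == "mouse-mouse"]
    if len(hh) and len(mm):
        stat, p = proportions_test(int(hh["significant"].sum()), len(hh),
                                   int(mm["significant"].sum()), len(mm))
        rows.append(dict(test="prop_significant_pairs_hh_vs_mm",
                         group1="human-human", group2="mouse-mouse",
                         statistic=stat, df=1, p=p))
    counts = partner_counts.set_index("dataset")["n_significant_partners"]
    humans = [d for d, s in species.items() if s == "human"]
    mice = [d for d, s in species.items() if s == "mouse"]
    if humans and mice:
        n_possible_h = (len(humans) + len(mice) - 1) * len(humans)
        n_possible_m = (len(humans) + len(mice) - 1) * len(mice)
        stat, p = proportions_test(int(counts[humans].sum()), n_possible_h,
                                   int(counts[mice].sum()), n_possible_m)
        rows.append(dict(test="prop_significant_partners_human_vs_mouse",
                         group1="human", group2="mouse",
                         statistic=stat, df=1, p=p))
    return pd.DataFrame(rows, columns=["test", "group1", "group2",
                                       "statistic", "df", "p"])
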