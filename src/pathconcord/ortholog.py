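"""Probe-to-symbol collapse and mouse-to-human symbol mapping.

Cross-species comparison needs every dataset in one namespace (human HUGO
symbols). Probe-level matrices are first collapsed to symbols — for each
symbol the probe with the largest across-sample mean is retained, the
conventional GSEA collapse default — and mouse symbols are then renamed to
their human orthologs, either via an explicit two-column table or, absent
one, by the uppercase heuristic (most mouse symbols differ from the human
ortholog only by case, e.g. Tlr4 -> TLR4).
"""

from __future__ import annotations

import logging

import pandas as pd

from .io_formats import ExpressionDataset

logger = logging.getLogger("pathconcord")

__all__ = ["collapse_probes", "map_mouse_to_human"]


def _collapse_max_mean(values: pd.DataFrame, symbols: pd.Series) -> pd.DataFrame:
    """Keep, per target symbol, the row with the largest across-sample mean.

    Ties are broken by lexicographically smallest source id so the result is
    platform-independent.
    """
    means = values.mean(axis=1)
    # sort by (symbol, -mean, id): first row per symbol is the winner
    order = pd.DataFrame({"symbol": symbols, "mean": means, "id": values.index})
    order = order.sort_values(["symbol", "mean", "id"],
                              ascending=[True, False, True], kind="mergesort")
    keep = order.drop_duplicates("symbol", keep="first")["id"]
    out = values.loc[keep]
    out.index = order.set_index("id").loc[keep, "symbol"].values
    return out.sort_index()


def collapse_probes(data: ExpressionDataset, probe_map: dict[str, str],
                    mode: str = "max_mean_probe") -> ExpressionDataset:
    """Collapse a probe-level matrix to gene symbols.

    Probes absent from ``probe_map`` are dropped (counted in the log). When
    several probes map to one symbol, the probe with the largest mean
    expression across all samples is retained (``max_mean_probe``, the only
    supported mode). Raises if no probe maps at all.
    """
    if mode != "max_mean_probe":
        raise ValueError(f"unsupported collapse mode {mode!r}")
    mapped = data.values.index.to_series().map(probe_map)
    unmapped = int(mapped.isna().sum())
    if unmapped:
        logger.info("collapse_probes: dropping %d/%d unmapped probes",
                    unmapped, data.n_features)
    kept = data.values.loc[mapped.notna()]
    if kept.empty:
        raise ValueError("no probe maps to a symbol; cannot collapse")
    out = _collapse_max_mean(kept, mapped.dropna())
    return ExpressionDataset(values=out, phenotype=data.phenotype,
                             case=data.case, control=data.control,
                             dataset_id=data.dataset_id)


def map_mouse_to_human(data: ExpressionDataset,
                       ortholog_map: dict[str, str] | None = None,
                       use_heuristic: bool = True) -> ExpressionDataset:
    """Rename mouse gene symbols to human (HUGO) symbols.

    With ``ortholog_map``, rows are renamed via the table and unmapped rows
    dropped. Without one (and ``use_heuristic``), symbols are uppercased.
    Many-to-one collisions are re-collapsed by the max-mean rule. An empty
    result is logged as a warning rather than raised: the gene-set size
    filter downstream reports it.
    """
    idx = data.values.index.to_series()
    if ortholog_map is not None:
        mapped = idx.map(ortholog_map)
        dropped = int(mapped.isna().sum())
        if dropped:
            logger.info("map_mouse_to_human: dropping %d/%d symbols absent "
                        "from the ortholog table", dropped, data.n_features)
        kept = data.values.loc[mapped.notna()]
        symbols = mapped.dropna()
    elif use_heuristic:
        kept = data.values
        symbols = idx.str.upper()
    else:
        raise ValueError("no ortholog table given and heuristic disabled")
    if kept.empty:
        logger.warning("map_mouse_to_human: no symbol mapped; empty dataset")
        out = kept
    else:
        out = _collapse_max_mean(kept, symbols)
    return ExpressionDataset(values=out, phenotype=data.phenotype,
                             case=data.case, control=data.control,
                             dataset_id=data.dataset_id)
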