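"""Three-state pathway-regulation calls from an enrichment table.

A pathway in one dataset is called ``up`` (NES > 0 and FDR q <= threshold),
``down`` (NES < 0 and q <= threshold) or ``null`` — not significantly
changed, or too few member genes detectable for testing. The default
threshold is q <= 0.25, the conventional GSEA exploratory cutoff (boundary
inclusive). A NES of exactly 0 has no direction and is ``null``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gsea import STATUS_TESTED
from .io_formats import GeneSetCollection

__all__ = ["PathwayStateProfile", "classify", "STATES"]

STATES = ("up", "down", "null")


@dataclass
class PathwayStateProfile:
    """Per-pathway regulation call for one dataset, with NES/q provenance.

    ``states``, ``nes`` and ``q`` are Series indexed by the full pathway
    collection; NES and q are NaN for pathways that were not tested.
    """

    dataset_id: str
    states: pd.Series
    nes: pd.Series
    q: pd.Series

    def __post_init__(self) -> None:
        bad = set(self.states.unique()) - set(STATES)
        if bad:
            raise ValueError(f"invalid states {sorted(bad)}")

    @property
    def pathways(self) -> pd.Index:
        return self.states.index

    def up_set(self) -> set[str]:
        return set(self.states.index[self.states == "up"])

    def down_set(self) -> set[str]:
        return set(self.states.index[self.states == "down"])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"pathway": self.states.index,
                             "state": self.states.values,
                             "nes": self.nes.values,
                             "q_fdr": self.q.values})


def classify(results: pd.DataFrame, collection: GeneSetCollection,
             fdr_threshold: float = 0.25,
             dataset_id: str = "dataset") -> PathwayStateProfile:
    """Convert a ``run_gsea`` table into a three-state profile.

    Every pathway of ``collection`` receives exactly one state; pathways in
    the table but absent from the collection are an error. Pathways missing
    from the table (not run) are ``null``, as are size-excluded and
    not-testable ones.
    """
    extra = set(results["set"]) - set(collection.names)
    if extra:
        raise ValueError(
            f"results contain pathways not in the collection: {sorted(extra)}")
    states = pd.Series("null", index=pd.Index(collection.names, name="pathway"))
    nes = pd.Series(np.nan, index=states.index)
    q = pd.Series(np.nan, index=states.index)
    for row in results.itertuples(index=False):
        if row.status != STATUS_TESTED:
            continue
        nes[row.set] = row.nes
        q[row.set] = row.q_fdr
        if row.q_fdr <= fdr_threshold:
            if row.nes > 0:
                states[row.set] = "up"
            elif row.nes < 0:
                states[row.set] = "down"
    return PathwayStateProfile(dataset_id=dataset_id, states=states,
                               nes=nes, q=q)
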