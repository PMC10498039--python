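"""Ejaculate-protein annotation: dataset assembly and candidate calling.

The working dataset is the set algebra of the detected proteins against
published ejaculate lists — sperm proteome (SpP), high-confidence and
candidate seminal fluid proteins (SFP) — minus proteins also recorded in
the female reproductive tract (FRT), whose origin is ambiguous.  New
candidate ejaculate proteins are called from a tissue-expression atlas:
genes strongly male-biased and strongly biased toward the accessory
glands (SFP candidates) or the testes (sperm candidates).
"""

from __future__ import annotations

from dataclasses import dataclass
from types import MappingProxyType
from typing import Mapping

import numpy as np
import pandas as pd

from .synth import AnnotationSets

__all__ = ["DatasetPartition", "assemble_datasets", "call_candidates"]

CLASS_SFP = "SFP"
CLASS_SPP = "SpP"
CLASS_DUAL = "dual"
CLASS_CANDIDATE = "candidate"

REQUIRED_TISSUE_COLUMNS = (
    "male_whole_body",
    "female_whole_body",
    "accessory_gland",
    "testis",
)


@dataclass(frozen=True)
class DatasetPartition:
    """Working / extended dataset membership with per-protein class labels."""

    working: frozenset[str]
    extended: frozenset[str]
    class_of: Mapping[str, str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "class_of", MappingProxyType(dict(self.class_of)))
        if set(self.class_of) != set(self.extended):
            raise ValueError("class labels must cover exactly the extended dataset")
        if not self.working <= self.extended:
            raise ValueError("working dataset must be contained in the extended one")

    def class_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for cls in self.class_of.values():
            sizes[cls] = sizes.get(cls, 0) + 1
        return sizes


def assemble_datasets(sets: AnnotationSets) -> DatasetPartition:
    """Assemble the working and extended datasets from annotation sets.

    ``working = (detected ∩ (SpP ∪ SFP)) \\ FRT`` and
    ``extended = working ∪ (detected ∩ called candidates)``.  Classes:
    SFP-annotated only → ``SFP``; sperm-annotated only → ``SpP``; both →
    ``dual``; called candidates → ``candidate``.
    """
    if not sets.detected:
        return DatasetPartition(frozenset(), frozenset(), {})
    if sets.called_spp_cand & sets.called_sfp_cand:
        raise ValueError("a protein appears in both called candidate sets")

    sfp = sets.sfp
    overlap = sets.detected & (sets.spp | sfp)
    working = overlap - sets.frt
    candidates = sets.detected & (sets.called_spp_cand | sets.called_sfp_cand)
    extended = working | candidates

    class_of: dict[str, str] = {}
    for pid in working:
        in_sfp, in_spp = pid in sfp, pid in sets.spp
        class_of[pid] = CLASS_DUAL if (in_sfp and in_spp) else (
            CLASS_SFP if in_sfp else CLASS_SPP
        )
    for pid in candidates:
        class_of[pid] = CLASS_CANDIDATE
    return DatasetPartition(frozenset(working), frozenset(extended), class_of)


def call_candidates(
    tissue_table: pd.DataFrame,
    sex_quantile: float = 0.90,
    tissue_tail: float = 0.10,
    pseudocount: float = 0.5,
) -> tuple[frozenset[str], frozenset[str]]:
    """Call candidate sperm and SFP genes from tissue-expression bias.

    Step 1 keeps genes whose male:female whole-body log-ratio lies
    strictly above the empirical ``sex_quantile`` of all genes in the
    table.  Step 2 splits the survivors by the accessory-gland : testis
    log-ratio — strictly above the upper ``tissue_tail`` quantile →
    SFP candidates, strictly below the lower quantile → sperm
    candidates.  Zeros are replaced by ``pseudocount`` before taking
    ratios; both quantiles are computed over every gene in the table, and
    boundary ties are excluded.

    Returns ``(spp_candidates, sfp_candidates)`` as frozensets of gene IDs.
    """
    missing = [c for c in REQUIRED_TISSUE_COLUMNS if c not in tissue_table.columns]
    if missing:
        raise ValueError(f"tissue table is missing columns: {missing}")
    if not (0 < sex_quantile < 1) or not (0 < tissue_tail < 0.5):
        raise ValueError("quantile arguments out of range")

    vals = tissue_table[list(REQUIRED_TISSUE_COLUMNS)].astype(float).copy()
    if (vals.to_numpy() < 0).any():
        raise ValueError("expression values must be non-negative")
    vals = vals.mask(vals <= 0, pseudocount)

    sex_lr = np.log2(vals["male_whole_body"] / vals["female_whole_body"])
    tissue_lr = np.log2(vals["accessory_gland"] / vals["testis"])

    male_biased = sex_lr > sex_lr.quantile(sex_quantile)
    ag_biased = tissue_lr > tissue_lr.quantile(1.0 - tissue_tail)
    te_biased = tissue_lr < tissue_lr.quantile(tissue_tail)

    sfp_cand = frozenset(tissue_table.index[male_biased & ag_biased])
    spp_cand = frozenset(tissue_table.index[male_biased & te_biased])
    return spp_cand, sfp_cand
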