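"""Synthetic TMT experiments with known ground truth.

This module generates everything the analysis pipeline consumes, with the
statistical structure of a multi-plex isobaric-labelling study of the
transferred *Drosophila* ejaculate proteome:

* a balanced sample design (isolines × larval diets × biological
  replicates) packed into 16-plex TMT experiments,
* protein-level reporter intensities built from additive log2 effects
  (baseline, isoline, diet, isoline×diet, plex batch, sample loading,
  residual noise) with whole-plex protein dropout,
* annotation-list fixtures (sperm proteome, seminal-fluid-protein lists,
  female-reproductive-tract proteome) with exact overlap cardinalities,
* a FlyAtlas2-like tissue expression table with planted candidate
  ejaculate proteins.

Every generator is deterministic given its seed, and every latent
quantity is returned as ground truth so downstream recovery can be
tested.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from itertools import product
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "DIET_HIGH",
    "DIET_LOW",
    "TruthParams",
    "GroundTruth",
    "OverlapMarginals",
    "AnnotationSets",
    "TissueFixture",
    "generate_design",
    "simulate_intensities",
    "generate_annotation_fixture",
    "generate_tissue_table",
]

DIET_HIGH = "high"
DIET_LOW = "low"

#: Study layout: 12 isolines x 2 diets x 3 replicates in five 16-plexes.
DEFAULT_N_ISOLINES = 12
DEFAULT_N_DIETS = 2
DEFAULT_N_REPLICATES = 3
DEFAULT_PLEX_SIZE = 16


# ---------------------------------------------------------------------------
# sample design
# ---------------------------------------------------------------------------

def generate_design(
    n_isolines: int = DEFAULT_N_ISOLINES,
    n_diets: int = DEFAULT_N_DIETS,
    n_replicates: int = DEFAULT_N_REPLICATES,
    plex_size: int = DEFAULT_PLEX_SIZE,
    seed: int = 0,
) -> pd.DataFrame:
    """Build the balanced sample design and pack it into TMT plexes.

    Samples are enumerated in (isoline, diet, replicate) order and dealt
    round-robin over ``ceil(total / plex_size)`` plexes, so the replicates
    of one (isoline, diet) cell land in distinct plexes whenever the plex
    count allows.  Channel numbers within a plex are a seeded permutation,
    standing in for an interference-aware channel layout.

    Returns a DataFrame indexed by ``sample_id`` with columns
    ``isoline, diet, replicate, plex, channel``.
    """
    for name, v in [("n_isolines", n_isolines), ("n_diets", n_diets),
                    ("n_replicates", n_replicates), ("plex_size", plex_size)]:
        if int(v) != v or v < 1:
            raise ValueError(f"{name} must be a positive integer, got {v!r}")

    isolines = [f"I{i + 1:02d}" for i in range(n_isolines)]
    if n_diets == 2:
        diets = [DIET_HIGH, DIET_LOW]
    else:
        diets = [f"diet{j + 1}" for j in range(n_diets)]
    total = n_isolines * n_diets * n_replicates
    n_plex = math.ceil(total / plex_size)

    rows = []
    for idx, (iso, diet, rep) in enumerate(
        product(isolines, diets, range(1, n_replicates + 1))
    ):
        rows.append(
            {
                "sample_id": f"{iso}_{diet}_r{rep}",
                "isoline": iso,
                "diet": diet,
                "replicate": rep,
                "plex": idx % n_plex + 1,
            }
        )
    design = pd.DataFrame(rows).set_index("sample_id")

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xD351]))
    channel = pd.Series(0, index=design.index)
    for k, samples in design.groupby("plex").groups.items():
        chans = rng.permutation(plex_size)[: len(samples)] + 1
        channel.loc[samples] = chans
    design["channel"] = channel
    return design


def validate_design(design: pd.DataFrame) -> None:
    """Raise ``ValueError`` if a design table violates its invariants."""
    required = {"isoline", "diet", "replicate", "plex", "channel"}
    missing = required - set(design.columns)
    if missing:
        raise ValueError(f"design is missing columns: {sorted(missing)}")
    counts = design.groupby(["isoline", "diet"], observed=True).size()
    if counts.nunique() != 1:
        raise ValueError("unbalanced design: unequal replicate counts per cell")
    if design.duplicated(["plex", "channel"]).any():
        raise ValueError("duplicate (plex, channel) assignment")


# ---------------------------------------------------------------------------
# intensity simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TruthParams:
    """Effect magnitudes for the intensity simulator (log2 units).

    Defaults emulate the deposited study structure: 4328 detected
    proteins of which 2547 are seen in all five plexes, 445 miss exactly
    one plex and 1336 miss more than one.  Effect standard deviations
    are chosen to give isoline-dominated variation with a weak diet main
    effect, moderate plex batch offsets and mild loading differences.
    """

    n_proteins: int = 4328
    #: (n_complete, n_single_missing, n_multi_missing); must sum to n_proteins
    dropout: tuple[int, int, int] = (2547, 445, 1336)
    baseline_mean: float = 14.0
    baseline_sd: float = 2.0
    isoline_sd: float = 0.5
    diet_sd: float = 0.1
    interaction_sd: float = 0.25
    batch_sd: float = 0.5
    loading_sd: float = 0.25
    sigma: float = 0.25
    #: optional explicit per-protein diet effects (overrides diet_sd draw)
    diet_effects: tuple[float, ...] | None = None

    def validate(self) -> None:
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")
        if len(self.dropout) != 3 or any(v < 0 for v in self.dropout):
            raise ValueError("dropout must be three non-negative counts")
        if sum(self.dropout) != self.n_proteins:
            raise ValueError(
                f"dropout partition {self.dropout} does not sum to "
                f"n_proteins={self.n_proteins}"
            )
        for name in ("isoline_sd", "diet_sd", "interaction_sd", "batch_sd",
                     "loading_sd", "sigma", "baseline_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.diet_effects is not None and len(self.diet_effects) != self.n_proteins:
            raise ValueError("diet_effects length must equal n_proteins")

    @classmethod
    def null(cls, n_proteins: int = 1000, **kw) -> "TruthParams":
        """No diet/isoline/interaction signal; batch + loading + noise only."""
        base = cls(n_proteins=n_proteins, dropout=(n_proteins, 0, 0),
                   isoline_sd=0.0, diet_sd=0.0, interaction_sd=0.0)
        return replace(base, **kw)

    @classmethod
    def batch_only(cls, n_proteins: int = 500, batch_sd: float = 0.5, **kw) -> "TruthParams":
        """Pure plex batch structure: all biological effects zero."""
        base = cls(n_proteins=n_proteins, dropout=(n_proteins, 0, 0),
                   isoline_sd=0.0, diet_sd=0.0, interaction_sd=0.0,
                   batch_sd=batch_sd, loading_sd=0.0, sigma=0.25)
        return replace(base, **kw)

    @classmethod
    def isoline_dominant(cls, n_proteins: int = 300, **kw) -> "TruthParams":
        """Genotype-dominated variance structure: isoline > G×E > diet."""
        base = cls(n_proteins=n_proteins, dropout=(n_proteins, 0, 0),
                   isoline_sd=1.0, interaction_sd=0.5, diet_sd=0.1,
                   batch_sd=0.3, sigma=0.3)
        return replace(base, **kw)

    @classmethod
    def diet_null(cls, n_proteins: int = 400, **kw) -> "TruthParams":
        """Diet-responsive only through G×E: no consistent across-isoline effect.

        Mirrors the observed structure of the study system — isolines
        respond to diet in different directions (weak interaction), so
        the diet main effect averaged over isolines is zero and no
        protein should survive FDR correction on the diet contrast.
        """
        base = cls(n_proteins=n_proteins, dropout=(n_proteins, 0, 0),
                   diet_sd=0.0, interaction_sd=0.1, isoline_sd=0.5)
        return replace(base, **kw)


@dataclass(frozen=True)
class GroundTruth:
    """Latent quantities behind one simulated experiment.

    All arrays are in log2 units.  ``isoline_dev`` and ``interaction_dev``
    sum to zero over isolines within each protein; ``missing_plexes`` maps a
    protein ID to the (possibly empty) tuple of plexes it was dropped from.
    """

    protein_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    isoline_levels: tuple[str, ...]
    plexes: tuple[int, ...]
    baseline: np.ndarray            # (P,)
    isoline_dev: np.ndarray         # (P, G)
    diet_effect: np.ndarray         # (P,)  high - low log2 fold change
    interaction_dev: np.ndarray     # (P, G)
    batch_offset: np.ndarray        # (P, K)
    loading_offset: np.ndarray      # (S,)
    noise: np.ndarray               # (P, S)
    sigma: float
    missing_plexes: Mapping[str, tuple[int, ...]] = field(default_factory=dict)

    def log2_expected(self, design: pd.DataFrame) -> pd.DataFrame:
        """Noise-free log2 surface for ``design`` (reconstruction check)."""
        iso_idx = np.array([self.isoline_levels.index(v) for v in design["isoline"]])
        plex_idx = np.array([self.plexes.index(v) for v in design["plex"]])
        x = np.where(design["diet"].to_numpy() == DIET_HIGH, 0.5, -0.5)
        vals = (
            self.baseline[:, None]
            + self.isoline_dev[:, iso_idx]
            + (self.diet_effect[:, None] + self.interaction_dev[:, iso_idx]) * x[None, :]
            + self.batch_offset[:, plex_idx]
            + self.loading_offset[None, :]
        )
        return pd.DataFrame(vals, index=list(self.protein_ids), columns=design.index)


def _centered_normal(rng: np.random.Generator, sd: float, shape: tuple[int, int]) -> np.ndarray:
    draw = rng.normal(0.0, sd, shape) if sd > 0 else np.zeros(shape)
    return draw - draw.mean(axis=1, keepdims=True)


def simulate_intensities(
    design: pd.DataFrame,
    params: TruthParams | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate a proteins × samples reporter-intensity matrix.

    Observed intensity is ``2 ** (mu + g + (d + gamma) * x + b + l + e)``
    with diet coded x = +1/2 (high) / −1/2 (low), so ``d`` is the
    high−low log2 fold change.  Missingness is applied at whole-plex
    granularity according to the dropout partition: complete proteins are
    observed in every plex, single-missing proteins are dropped from one
    random plex and multi-missing from 2 … K−1 random plexes.

    Returns the intensity matrix (NaN = missing) and the ground truth.
    """
    params = params or TruthParams()
    params.validate()
    validate_design(design)

    isolines = tuple(sorted(design["isoline"].unique()))
    plexes = tuple(sorted(design["plex"].unique()))
    P, S, G, K = params.n_proteins, len(design), len(isolines), len(plexes)
    n_complete, n_single, n_multi = params.dropout
    if n_single and K < 2:
        raise ValueError("single-plex dropout requires >= 2 plexes")
    if n_multi and K < 3:
        raise ValueError("multi-plex dropout requires >= 3 plexes")

    ss = np.random.SeedSequence([int(seed), 0x51B])
    rng_eff, rng_noise, rng_drop = (np.random.default_rng(s) for s in ss.spawn(3))

    protein_ids = tuple(f"P{i + 1:05d}" for i in range(P))
    baseline = rng_eff.normal(params.baseline_mean, params.baseline_sd, P)
    g = _centered_normal(rng_eff, params.isoline_sd, (P, G))
    if params.diet_effects is not None:
        d = np.asarray(params.diet_effects, dtype=float)
    elif params.diet_sd > 0:
        d = rng_eff.normal(0.0, params.diet_sd, P)
    else:
        d = np.zeros(P)
    gamma = _centered_normal(rng_eff, params.interaction_sd, (P, G))
    b = rng_eff.normal(0.0, params.batch_sd, (P, K)) if params.batch_sd > 0 else np.zeros((P, K))
    l = rng_eff.normal(0.0, params.loading_sd, S) if params.loading_sd > 0 else np.zeros(S)
    e = rng_noise.normal(0.0, params.sigma, (P, S)) if params.sigma > 0 else np.zeros((P, S))

    iso_idx = np.array([isolines.index(v) for v in design["isoline"]])
    plex_idx = np.array([plexes.index(v) for v in design["plex"]])
    x = np.where(design["diet"].to_numpy() == DIET_HIGH, 0.5, -0.5)

    log2v = (
        baseline[:, None]
        + g[:, iso_idx]
        + (d[:, None] + gamma[:, iso_idx]) * x[None, :]
        + b[:, plex_idx]
        + l[None, :]
        + e
    )
    values = np.exp2(log2v)

    # whole-plex dropout with exact partition marginals
    order = rng_drop.permutation(P)
    missing: dict[str, tuple[int, ...]] = {}
    plex_cols = {k: np.flatnonzero(design["plex"].to_numpy() == k) for k in plexes}
    for pos in order[n_complete : n_complete + n_single]:
        k = plexes[rng_drop.integers(K)]
        missing[protein_ids[pos]] = (k,)
        values[pos, plex_cols[k]] = np.nan
    for pos in order[n_complete + n_single :]:
        m = int(rng_drop.integers(2, K))
        ks = tuple(sorted(plexes[i] for i in rng_drop.choice(K, size=m, replace=False)))
        missing[protein_ids[pos]] = ks
        for k in ks:
            values[pos, plex_cols[k]] = np.nan

    matrix = pd.DataFrame(values, index=list(protein_ids), columns=design.index)
    matrix.index.name = "protein_id"
    truth = GroundTruth(
        protein_ids=protein_ids,
        sample_ids=tuple(design.index),
        isoline_levels=isolines,
        plexes=plexes,
        baseline=baseline,
        isoline_dev=g,
        diet_effect=d,
        interaction_dev=gamma,
        batch_offset=b,
        loading_offset=l,
        noise=e,
        sigma=params.sigma,
        missing_plexes=missing,
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# annotation fixture
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OverlapMarginals:
    """Cardinalities of the annotation-set Venn atoms within the detected set.

    Defaults reproduce the study's published counts: 2992 retained
    proteins, of which 1284 overlap the sperm-proteome/SFP lists; 636 of
    those are shared with the female reproductive tract, leaving a
    648-protein working set (140 SFP-only, 433 sperm-only, 75 dual); 24
    sperm and 27 SFP candidates are called on top, giving 699.
    """

    n_detected: int = 2992
    n_spp: int = 2288
    n_sfp_high: int = 311
    n_sfp_candidate_list: int = 314
    n_spp_sfp_shared: int = 188
    # composition of detected ∩ (SpP ∪ SFP), FRT-clean part
    n_sfp_only_clean: int = 140
    n_spp_only_clean: int = 433
    n_dual_clean: int = 75
    # composition of the FRT-shared part
    n_sfp_only_frt: int = 160
    n_dual_frt: int = 113
    n_spp_only_frt: int = 363
    # called candidates (detected, outside all published lists)
    n_spp_cand_called: int = 24
    n_sfp_cand_called: int = 27
    # FRT proteins outside the ejaculate overlap (not detected)
    n_frt_extra: int = 300

    @property
    def n_overlap(self) -> int:
        return (self.n_sfp_only_clean + self.n_spp_only_clean + self.n_dual_clean
                + self.n_sfp_only_frt + self.n_dual_frt + self.n_spp_only_frt)

    @property
    def n_frt_in_overlap(self) -> int:
        return self.n_sfp_only_frt + self.n_dual_frt + self.n_spp_only_frt

    def validate(self) -> None:
        counts = [v for v in self.__dict__.values()]
        if any(int(v) != v or v < 0 for v in counts):
            raise ValueError("all marginals must be non-negative integers")
        n_sfp_union = self.n_sfp_high + self.n_sfp_candidate_list
        n_dual = self.n_dual_clean + self.n_dual_frt
        n_sfp_only = self.n_sfp_only_clean + self.n_sfp_only_frt
        n_spp_only = self.n_spp_only_clean + self.n_spp_only_frt
        called = self.n_spp_cand_called + self.n_sfp_cand_called
        if n_dual > self.n_spp_sfp_shared:
            raise ValueError("detected dual proteins exceed the shared SpP∩SFP list")
        if self.n_spp_sfp_shared > min(self.n_spp, n_sfp_union):
            raise ValueError("SpP∩SFP overlap exceeds a parent list")
        if n_sfp_only + self.n_spp_sfp_shared > n_sfp_union:
            raise ValueError("detected SFP-only proteins exceed the SFP lists")
        if n_spp_only + self.n_spp_sfp_shared > self.n_spp:
            raise ValueError("detected SpP-only proteins exceed the sperm proteome")
        if self.n_overlap + called > self.n_detected:
            raise ValueError("overlap plus called candidates exceed detected set")


@dataclass(frozen=True)
class AnnotationSets:
    """Named protein-ID sets used by the dataset assembly."""

    detected: frozenset[str]
    spp: frozenset[str]
    sfp_high: frozenset[str]
    sfp_candidate_list: frozenset[str]
    frt: frozenset[str]
    called_spp_cand: frozenset[str] = frozenset()
    called_sfp_cand: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        published = self.spp | self.sfp_high | self.sfp_candidate_list | self.frt
        called = self.called_spp_cand | self.called_sfp_cand
        if called & published:
            raise ValueError("called candidates must be disjoint from published lists")

    @property
    def sfp(self) -> frozenset[str]:
        """Union of the high-confidence and candidate SFP lists."""
        return self.sfp_high | self.sfp_candidate_list


def generate_annotation_fixture(
    marginals: OverlapMarginals | None = None,
    seed: int = 0,
) -> AnnotationSets:
    """Build synthetic ID sets whose overlap cardinalities match exactly.

    IDs are opaque ``FBpp``-style labels assigned from a seeded shuffle,
    so identical marginals and seed give bit-identical sets.
    """
    m = marginals or OverlapMarginals()
    m.validate()

    atoms = {
        "sfp_only_clean": m.n_sfp_only_clean,
        "spp_only_clean": m.n_spp_only_clean,
        "dual_clean": m.n_dual_clean,
        "sfp_only_frt": m.n_sfp_only_frt,
        "dual_frt": m.n_dual_frt,
        "spp_only_frt": m.n_spp_only_frt,
        "cand_spp": m.n_spp_cand_called,
        "cand_sfp": m.n_sfp_cand_called,
        "detected_plain": m.n_detected - m.n_overlap
        - m.n_spp_cand_called - m.n_sfp_cand_called,
        # undetected remainder of each published list
        "spp_extra": m.n_spp - (m.n_spp_only_clean + m.n_spp_only_frt + m.n_spp_sfp_shared),
        "sfp_extra": (m.n_sfp_high + m.n_sfp_candidate_list)
        - (m.n_sfp_only_clean + m.n_sfp_only_frt + m.n_spp_sfp_shared),
        "dual_extra": m.n_spp_sfp_shared - (m.n_dual_clean + m.n_dual_frt),
        "frt_extra": m.n_frt_extra,
    }
    total = sum(atoms.values())
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xA110]))
    ids = [f"FBpp{i:07d}" for i in rng.permutation(total)]
    pools: dict[str, list[str]] = {}
    cursor = 0
    for name in sorted(atoms):
        pools[name] = ids[cursor : cursor + atoms[name]]
        cursor += atoms[name]

    detected = (
        pools["sfp_only_clean"] + pools["spp_only_clean"] + pools["dual_clean"]
        + pools["sfp_only_frt"] + pools["dual_frt"] + pools["spp_only_frt"]
        + pools["cand_spp"] + pools["cand_sfp"] + pools["detected_plain"]
    )
    spp = (
        pools["spp_only_clean"] + pools["spp_only_frt"] + pools["dual_clean"]
        + pools["dual_frt"] + pools["dual_extra"] + pools["spp_extra"]
    )
    sfp_all = (
        pools["sfp_only_clean"] + pools["sfp_only_frt"] + pools["dual_clean"]
        + pools["dual_frt"] + pools["dual_extra"] + pools["sfp_extra"]
    )
    sfp_all = list(rng.permutation(sorted(sfp_all)))
    frt = pools["sfp_only_frt"] + pools["dual_frt"] + pools["spp_only_frt"] + pools["frt_extra"]

    return AnnotationSets(
        detected=frozenset(detected),
        spp=frozenset(spp),
        sfp_high=frozenset(sfp_all[: m.n_sfp_high]),
        sfp_candidate_list=frozenset(sfp_all[m.n_sfp_high :]),
        frt=frozenset(frt),
        called_spp_cand=frozenset(pools["cand_spp"]),
        called_sfp_cand=frozenset(pools["cand_sfp"]),
    )


# ---------------------------------------------------------------------------
# tissue expression fixture
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TissueFixture:
    """Tissue-expression table plus the planted candidate ground truth."""

    table: pd.DataFrame
    planted_spp: frozenset[str]
    planted_sfp: frozenset[str]


def generate_tissue_table(
    n_genes: int = 1000,
    n_planted_spp: int = 24,
    n_planted_sfp: int = 27,
    seed: int = 0,
    sex_quantile: float = 0.90,
    tissue_tail: float = 0.10,
) -> TissueFixture:
    """FlyAtlas2-like expression table with planted candidate genes.

    Planted SFP candidates are strongly male-biased and accessory-gland
    biased; planted sperm candidates male-biased and testis-biased.
    Filler genes occupy the quantile tails singly (male-biased but
    tissue-neutral, or tissue-extreme but not male-biased) so that the
    planted genes — and only they — pass both calling filters at the
    given quantiles.  Columns: male/female whole body, accessory gland,
    testis, carcass.
    """
    n_planted = n_planted_spp + n_planted_sfp
    if n_planted > n_genes:
        raise ValueError("planted candidates exceed n_genes")
    n_sex_tail = math.ceil(n_genes * (1.0 - sex_quantile))
    n_tissue_tail = math.ceil(n_genes * tissue_tail)
    if n_planted >= n_sex_tail:
        raise ValueError("too many planted genes for the sex-bias tail")
    if max(n_planted_spp, n_planted_sfp) >= n_tissue_tail:
        raise ValueError("too many planted genes for the tissue-bias tail")
    n_filler = n_sex_tail + 2 * n_tissue_tail
    if n_planted + n_filler > n_genes:
        raise ValueError("n_genes too small for the requested tail structure")

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x7155]))
    gene_ids = [f"FBgn{i:07d}" for i in rng.permutation(n_genes)]

    sex_lr = np.empty(n_genes)
    tissue_lr = np.empty(n_genes)
    # layout: [planted_sfp | planted_spp | sex filler | AG filler | testis filler | rest]
    a = 0
    sl = {}
    for name, size in [("sfp", n_planted_sfp), ("spp", n_planted_spp),
                       ("sex_fill", n_sex_tail), ("ag_fill", n_tissue_tail),
                       ("te_fill", n_tissue_tail)]:
        sl[name] = slice(a, a + size)
        a += size
    sl["rest"] = slice(a, n_genes)

    sex_lr[sl["sfp"]] = rng.uniform(5.0, 6.0, n_planted_sfp)
    sex_lr[sl["spp"]] = rng.uniform(5.0, 6.0, n_planted_spp)
    sex_lr[sl["sex_fill"]] = rng.uniform(3.0, 4.0, n_sex_tail)
    sex_lr[sl["ag_fill"]] = rng.uniform(-2.0, 0.0, n_tissue_tail)
    sex_lr[sl["te_fill"]] = rng.uniform(-2.0, 0.0, n_tissue_tail)
    sex_lr[sl["rest"]] = rng.uniform(-2.0, 2.0, n_genes - a)

    tissue_lr[sl["sfp"]] = rng.uniform(5.0, 6.0, n_planted_sfp)
    tissue_lr[sl["spp"]] = rng.uniform(-6.0, -5.0, n_planted_spp)
    tissue_lr[sl["sex_fill"]] = rng.uniform(-1.0, 1.0, n_sex_tail)
    tissue_lr[sl["ag_fill"]] = rng.uniform(4.0, 4.5, n_tissue_tail)
    tissue_lr[sl["te_fill"]] = rng.uniform(-4.5, -4.0, n_tissue_tail)
    tissue_lr[sl["rest"]] = rng.uniform(-1.0, 1.0, n_genes - a)

    female = np.exp2(rng.uniform(5.0, 8.0, n_genes))
    male = female * np.exp2(sex_lr)
    testis = np.exp2(rng.uniform(5.0, 8.0, n_genes))
    accessory = testis * np.exp2(tissue_lr)
    carcass = np.exp2(rng.uniform(5.0, 8.0, n_genes))

    table = pd.DataFrame(
        {
            "male_whole_body": male,
            "female_whole_body": female,
            "accessory_gland": accessory,
            "testis": testis,
            "carcass": carcass,
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    return TissueFixture(
        table=table,
        planted_spp=frozenset(gene_ids[i] for i in range(*sl["spp"].indices(n_genes))),
        planted_sfp=frozenset(gene_ids[i] for i in range(*sl["sfp"].indices(n_genes))),
    )
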