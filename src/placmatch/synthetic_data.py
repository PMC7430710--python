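"""Generator of study-like mare/stallion/foal datasets.

Emulates the statistical structure of the cohort the pipeline analyses:
nine tightly linked MHC microsatellite loci on one chromosome, founders
drawn as two haplotypes from a small pool (which induces the strong
pairwise linkage disequilibrium characteristic of a conserved MHC region),
Mendelian transmission with optional recombination between adjacent loci,
heritable null alleles (assigned on founder haplotypes, masked at
observation: one null copy makes the genotype appear homozygous, two make
it missing), a configurable logistic model tying RFM risk to the foal/dam
true compatibility categories, and pedigrees that are either fully outbred
or contain half-sib matings tuned to a target mean inbreeding coefficient.

Defaults mirror the study conditions: 43 mare-foal pairs, ~33% RFM
prevalence (intercept logit(14/43), no compatibility effect), null-allele
frequencies 0.14 at COR110 and 0.15 at TKY3324, a 12-haplotype founder
pool structured into five haplotype families, and weak recombination
(0.005 per adjacent-locus gap) within the region.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .compatibility import category_from_flags
from .errors import ValidationError
from .genotype_io import (
    GenotypeTable,
    LocusPanel,
    PairRecord,
    default_panel,
    write_genepop,
    write_genotypes_csv,
    write_pairs,
)
from .pedigree import Pedigree

__all__ = [
    "SimulationConfig",
    "SimulatedStudy",
    "default_haplotype_pool",
    "simulate_study",
    "emit_study_files",
]

NULL = 0  # internal marker for a non-amplifying allele on a true haplotype

Haplotype = tuple[int, ...]


#: Twelve founder haplotypes in five families; members of a family differ at
#: one or two loci only. Family structure gives realistic within-region LD
#: while allele sharing across haplotypes (microsatellite size homoplasy)
#: decouples class I and class II compatibility categories, as observed in
#: real cohorts. Allele lengths sit on a 2-bp grid inside each locus's
#: amplicon size range; the order of loci matches the default panel.
_DEFAULT_POOL: list[tuple[Haplotype, float]] = [
    ((203, 241, 207, 232, 331, 250, 227, 158, 153), 0.102),
    ((193, 241, 207, 232, 331, 250, 227, 158, 153), 0.107),
    ((203, 241, 207, 230, 331, 250, 227, 158, 153), 0.021),
    ((199, 239, 201, 230, 335, 252, 233, 166, 149), 0.075),
    ((199, 239, 201, 230, 335, 248, 233, 166, 149), 0.074),
    ((199, 239, 201, 236, 335, 258, 233, 166, 149), 0.021),
    ((203, 247, 199, 234, 339, 258, 225, 168, 149), 0.084),
    ((203, 249, 199, 234, 339, 258, 233, 168, 149), 0.078),
    ((195, 247, 205, 230, 339, 258, 229, 160, 149), 0.217),
    ((195, 247, 205, 230, 331, 258, 229, 160, 149), 0.109),
    ((193, 239, 205, 234, 333, 250, 235, 164, 153), 0.078),
    ((193, 243, 205, 234, 333, 250, 235, 162, 153), 0.034),
]


def default_haplotype_pool(panel: LocusPanel | None = None) -> list[tuple[Haplotype, float]]:
    """The default founder haplotype pool (12 haplotypes in 5 families).

    Defined for the default nine-locus panel; custom panels of the same
    length reuse the allele layout positionally.
    """
    panel = panel or default_panel()
    if len(panel) != 9:
        raise ValidationError("the default haplotype pool requires a nine-locus panel")
    return [(hap, freq) for hap, freq in _DEFAULT_POOL]


def _default_rfm_model() -> dict[str, float]:
    # intercept at the study prevalence 14/43; no compatibility effect
    return {
        "beta0": math.log(14 / 29),
        "beta_mcfc_i": 0.0,
        "beta_mfc_i": 0.0,
        "beta_mcfc_ii": 0.0,
        "beta_mfc_ii": 0.0,
    }


def _default_null_freqs(panel: LocusPanel) -> dict[str, float]:
    defaults = {"COR110": 0.14, "TKY3324": 0.15}
    return {l.name: defaults.get(l.name, 0.0) for l in panel}


@dataclass
class SimulationConfig:
    """Parameters of one simulated study; same seed means identical outputs."""

    seed: int
    n_pairs: int = 43
    panel: LocusPanel = field(default_factory=default_panel)
    haplotype_pool: list[tuple[Haplotype, float]] | None = None
    recombination_rates: Sequence[float] | None = None  # one per adjacent-locus gap
    null_allele_freq: dict[str, float] | None = None
    rfm_model: dict[str, float] = field(default_factory=_default_rfm_model)
    pedigree_scenario: str = "outbred"  # "outbred" | "loops"
    target_f: float = 0.01  # mean F aimed for under the loops scenario
    n_stallions: int | None = None  # default keeps the cohort's 43:6 mare:stallion ratio

    def __post_init__(self) -> None:
        if self.n_pairs < 1:
            raise ValidationError("n_pairs must be positive")
        if self.haplotype_pool is None:
            self.haplotype_pool = default_haplotype_pool(self.panel)
        if not self.haplotype_pool:
            raise ValidationError("haplotype pool must be non-empty")
        total = sum(f for _, f in self.haplotype_pool)
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"haplotype frequencies sum to {total}, not 1")
        for hap, _ in self.haplotype_pool:
            if len(hap) != len(self.panel):
                raise ValidationError("haplotype length must match the panel")
        if self.recombination_rates is None:
            self.recombination_rates = [0.005] * (len(self.panel) - 1)
        if len(self.recombination_rates) != len(self.panel) - 1:
            raise ValidationError("need one recombination rate per adjacent-locus gap")
        if any(not (0.0 <= r <= 0.5) for r in self.recombination_rates):
            raise ValidationError("recombination rates must lie in [0, 0.5]")
        if self.null_allele_freq is None:
            self.null_allele_freq = _default_null_freqs(self.panel)
        for locus, r in self.null_allele_freq.items():
            if locus not in self.panel:
                raise ValidationError(f"null frequency for unknown locus {locus!r}")
            if not (0.0 <= r < 1.0):
                raise ValidationError(f"null frequency at {locus} must be in [0, 1)")
        if self.pedigree_scenario not in ("outbred", "loops"):
            raise ValidationError(f"unknown pedigree scenario {self.pedigree_scenario!r}")
        if self.n_stallions is None:
            self.n_stallions = max(1, round(self.n_pairs * 6 / 43))
        if self.n_stallions < 1:
            raise ValidationError("n_stallions must be positive")


@dataclass
class SimulatedStudy:
    """One simulated cohort plus the ground truth behind it."""

    genotypes: GenotypeTable  # observed calls (nulls masked) for mares, stallions, foals
    pairs: list[PairRecord]
    pedigree: Pedigree
    truth: dict  # true haplotypes/genotypes, categories, RFM probabilities, parameters


def _draw_founder(pool, freqs_cum, null_rates, rng) -> tuple[list[int], list[int]]:
    haps = []
    for _ in range(2):
        idx = int(np.searchsorted(freqs_cum, rng.random(), side="right"))
        hap = list(pool[idx][0])
        for l, r in enumerate(null_rates):
            if r > 0.0 and rng.random() < r:
                hap[l] = NULL
        haps.append(hap)
    return haps[0], haps[1]


def _gamete(hap1: Sequence[int], hap2: Sequence[int], rates, rng) -> list[int]:
    current = int(rng.integers(2))
    out = []
    for l in range(len(hap1)):
        if l > 0 and rng.random() < rates[l - 1]:
            current = 1 - current
        out.append((hap1, hap2)[current][l])
    return out


def _observe(a: int, b: int) -> tuple[int, int] | None:
    visible = [x for x in (a, b) if x != NULL]
    if not visible:
        return None
    if len(visible) == 1:
        return (visible[0], visible[0])
    return (min(a, b), max(a, b))


def _true_category(mare_geno, foal_geno, loci_idx) -> str:
    flags = []
    for l in loci_idx:
        mare_set = set(mare_geno[l])
        foal_set = set(foal_geno[l])
        flags.append((foal_set <= mare_set, mare_set <= foal_set))
    return category_from_flags(flags)


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    """Simulate founders, trios, observed genotypes, RFM outcomes and a pedigree."""
    panel = config.panel
    n = config.n_pairs
    ss = np.random.SeedSequence(config.seed)
    rng_founders, rng_meiosis, rng_rfm, rng_assign = [
        np.random.default_rng(s) for s in ss.spawn(4)
    ]
    pool = config.haplotype_pool
    freqs_cum = np.cumsum([f for _, f in pool])
    null_rates = [config.null_allele_freq.get(l.name, 0.0) for l in panel]
    loci_i = [i for i, l in enumerate(panel) if l.mhc_class == "I"]
    loci_ii = [i for i, l in enumerate(panel) if l.mhc_class == "II"]

    mare_ids = [f"M{i+1:04d}" for i in range(n)]
    foal_ids = [f"F{i+1:04d}" for i in range(n)]
    if config.pedigree_scenario == "loops":
        stallion_ids = [f"S{i+1:04d}" for i in range(n)]
        assignment = list(range(n))
        n_looped = int(round(min(1.0, config.target_f / 0.125) * n))
    else:
        stallion_ids = [f"S{i+1:04d}" for i in range(config.n_stallions)]
        assignment = [int(a) for a in rng_assign.integers(config.n_stallions, size=n)]
        n_looped = 0

    haplos: dict[str, tuple[list[int], list[int]]] = {}
    for ind in mare_ids + stallion_ids:
        haplos[ind] = _draw_founder(pool, freqs_cum, null_rates, rng_founders)

    parents: dict[str, tuple[str | None, str | None]] = {
        ind: (None, None) for ind in mare_ids + stallion_ids
    }
    # half-sib matings: mare and her stallion share a grandsire founder
    for i in range(n_looped):
        grandsire = f"G{i+1:04d}"
        parents[grandsire] = (None, None)
        parents[f"GDm{i+1:04d}"] = (None, None)
        parents[f"GDs{i+1:04d}"] = (None, None)
        parents[mare_ids[i]] = (grandsire, f"GDm{i+1:04d}")
        parents[stallion_ids[i]] = (grandsire, f"GDs{i+1:04d}")

    true_genotypes: dict[str, list[tuple[int, int]]] = {}
    for ind in mare_ids + stallion_ids:
        h1, h2 = haplos[ind]
        true_genotypes[ind] = [(h1[l], h2[l]) for l in range(len(panel))]

    pairs: list[PairRecord] = []
    truth_categories: dict[str, dict[str, str]] = {}
    rfm_probs: dict[str, float] = {}
    beta = config.rfm_model
    for i in range(n):
        mare, foal = mare_ids[i], foal_ids[i]
        stallion = stallion_ids[assignment[i]]
        maternal = _gamete(*haplos[mare], config.recombination_rates, rng_meiosis)
        paternal = _gamete(*haplos[stallion], config.recombination_rates, rng_meiosis)
        true_genotypes[foal] = list(zip(maternal, paternal))
        parents[foal] = (stallion, mare)
        cat_i = _true_category(true_genotypes[mare], true_genotypes[foal], loci_i)
        cat_ii = _true_category(true_genotypes[mare], true_genotypes[foal], loci_ii)
        truth_categories[foal] = {"I": cat_i, "II": cat_ii}
        eta = beta["beta0"]
        eta += beta["beta_mcfc_i"] * (cat_i in ("MC", "FC")) + beta["beta_mfc_i"] * (cat_i == "MFC")
        eta += beta["beta_mcfc_ii"] * (cat_ii in ("MC", "FC")) + beta["beta_mfc_ii"] * (
            cat_ii == "MFC"
        )
        p = 1.0 / (1.0 + math.exp(-eta))
        rfm_probs[foal] = p
        pairs.append(PairRecord(mare, foal, bool(rng_rfm.random() < p)))

    table = GenotypeTable([l.name for l in panel])
    for ind in mare_ids + stallion_ids + foal_ids:
        table.add_individual(ind)
        for l, locus in enumerate(panel):
            call = _observe(*true_genotypes[ind][l])
            if call is not None:
                table.set_call(ind, locus.name, *call)

    truth = {
        "config": {
            "seed": config.seed,
            "n_pairs": config.n_pairs,
            "recombination_rates": list(config.recombination_rates),
            "null_allele_freq": dict(config.null_allele_freq),
            "rfm_model": dict(beta),
            "pedigree_scenario": config.pedigree_scenario,
            "target_f": config.target_f,
            "haplotype_pool": [[list(h), f] for h, f in pool],
        },
        "stallion_of_foal": {foal_ids[i]: stallion_ids[assignment[i]] for i in range(n)},
        "true_genotypes": {
            ind: [list(g) for g in genos] for ind, genos in true_genotypes.items()
        },
        "categories": truth_categories,
        "rfm_prob": rfm_probs,
    }
    return SimulatedStudy(table, pairs, Pedigree(parents), truth)


def emit_study_files(study: SimulatedStudy, out_dir: str | Path) -> dict[str, Path]:
    """Write genotypes (CSV + GenePop), pairs, pedigree and truth JSON to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "genotypes_csv": out / "genotypes.csv",
        "genotypes_genepop": out / "genotypes.gen",
        "pairs": out / "pairs.csv",
        "pedigree": out / "pedigree.csv",
        "truth": out / "truth.json",
    }
    write_genotypes_csv(study.genotypes, paths["genotypes_csv"])
    write_genepop(study.genotypes, paths["genotypes_genepop"], title="placmatch simulated study")
    write_pairs(study.pairs, paths["pairs"])
    study.pedigree.to_csv(paths["pedigree"])
    paths["truth"].write_text(json.dumps(study.truth, indent=2, sort_keys=True) + "\n")
    return paths
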