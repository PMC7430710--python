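"""Locus-level quality statistics for microsatellite panels.

Implements the conditional exact test for Hardy-Weinberg proportions
(probability test: the p-value is the total conditional probability, given
the observed allele counts, of all genotype arrays no more probable than
the observed one), by full enumeration when the array space is small and
otherwise by Monte Carlo — independent draws from the exact conditional
null obtained by randomly re-pairing the observed gene copies, organised
in GENEPOP-style batches whose means give the standard error; a
permutation exact test of genotypic linkage disequilibrium between locus
pairs; observed and unbiased expected heterozygosity; and three
null-allele frequency estimators (Chakraborty, Brookfield-1, and an
iterative estimator in the Summers-Amos/CERVUS tradition).
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .genotype_io import GenotypeTable, LocusPanel, default_panel

__all__ = [
    "MCParams",
    "HWEResult",
    "LDResult",
    "genotype_counts",
    "observed_heterozygosity",
    "expected_heterozygosity",
    "hwe_exact_test",
    "ld_genotypic_test",
    "null_allele_frequency",
    "locus_qc",
    "ld_pairwise",
]

_LOG2 = math.log(2.0)
_LOG_TOL = 1e-9  # "no more probable" comparisons in log space

GenotypeCounts = Mapping[tuple[int, int], int]


@dataclass(frozen=True)
class MCParams:
    """GENEPOP-style Markov chain parameters for the stochastic tests."""

    dememorization: int = 1000
    batches: int = 100
    iterations: int = 1000

    def __post_init__(self) -> None:
        if min(self.dememorization, self.batches, self.iterations) <= 0:
            raise ValidationError("Monte-Carlo parameters must all be positive")

    @property
    def total(self) -> int:
        return self.batches * self.iterations


@dataclass(frozen=True)
class HWEResult:
    p: float
    method: str  # "enumeration" | "monte_carlo" | "degenerate"
    testable: bool
    se: float | None = None


@dataclass(frozen=True)
class LDResult:
    p: float
    n_permutations: int
    testable: bool


def genotype_counts(
    table: GenotypeTable, locus: str, individuals: Sequence[str] | None = None
) -> dict[tuple[int, int], int]:
    """Genotype counts at one locus (keys are sorted allele pairs), missing excluded."""
    inds = individuals if individuals is not None else table.individuals
    counts: Counter[tuple[int, int]] = Counter()
    for ind in inds:
        call = table.get(ind, locus)
        if call is not None:
            counts[call] += 1
    return dict(counts)


def _allele_counts(counts: GenotypeCounts) -> dict[int, int]:
    out: Counter[int] = Counter()
    for (a, b), c in counts.items():
        out[a] += c
        out[b] += c
    return dict(out)


def _validate_counts(counts: GenotypeCounts) -> None:
    for (a, b), c in counts.items():
        if c < 0 or c != int(c):
            raise ValidationError(f"genotype count for ({a},{b}) must be a non-negative integer")
        if a > b:
            raise ValidationError(f"genotype key ({a},{b}) must be sorted")


def observed_heterozygosity(counts: GenotypeCounts) -> float:
    n = sum(counts.values())
    if n == 0:
        raise ValidationError("no genotypes")
    het = sum(c for (a, b), c in counts.items() if a != b)
    return het / n


def expected_heterozygosity(counts: GenotypeCounts, unbiased: bool = True) -> float:
    """Expected heterozygosity 1 - sum p_i^2; Nei's small-sample correction by default."""
    allele = _allele_counts(counts)
    total = sum(allele.values())
    if total == 0:
        raise ValidationError("no genotypes")
    h = 1.0 - sum((c / total) ** 2 for c in allele.values())
    if unbiased and total > 1:
        h *= total / (total - 1)
    return h


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact probability test.


def _log_cond_prob(counts: GenotypeCounts) -> float:
    """Log conditional probability of a genotype array given its allele counts.

    P = n! * prod_i(c_i!) * 2^het / ((2n)! * prod_g(a_g!)) — the Levene
    distribution induced by random pairing of the 2n gene copies.
    """
    n = sum(counts.values())
    allele = _allele_counts(counts)
    lp = math.lgamma(n + 1) - math.lgamma(2 * n + 1)
    for c in allele.values():
        lp += math.lgamma(c + 1)
    for (a, b), c in counts.items():
        lp -= math.lgamma(c + 1)
        if a != b:
            lp += c * _LOG2
    return lp


def _enumerate_arrays(allele_counts: dict[int, int], max_nodes: int):
    """Yield every genotype array (dict) with the given allele counts.

    Depth-first over genotype categories in lexicographic order; raises
    ``_EnumerationOverflow`` after ``max_nodes`` completed arrays.
    """
    alleles = sorted(allele_counts)
    cats = [(alleles[i], alleles[j]) for i in range(len(alleles)) for j in range(i, len(alleles))]
    yielded = 0

    def rec(idx: int, remaining: dict[int, int], current: dict[tuple[int, int], int]):
        nonlocal yielded
        if idx == len(cats):
            if all(v == 0 for v in remaining.values()):
                yielded += 1
                if yielded > max_nodes:
                    raise _EnumerationOverflow
                yield dict(current)
            return
        a, b = cats[idx]
        # copies of a still assignable by later categories involving a
        later_with_a = [c for c in cats[idx + 1:] if a in c]
        if a == b:
            hi = remaining[a] // 2
        else:
            hi = min(remaining[a], remaining[b])
        lo = 0
        if not later_with_a:
            # last category using allele a: it must consume all remaining copies of a
            need = remaining[a]
            if a == b:
                if need % 2:
                    return
                lo = hi = need // 2
            else:
                if need > remaining[b]:
                    return
                lo = hi = need
        for k in range(lo, hi + 1):
            if a == b:
                remaining[a] -= 2 * k
            else:
                remaining[a] -= k
                remaining[b] -= k
            if k:
                current[(a, b)] = k
            yield from rec(idx + 1, remaining, current)
            if k:
                del current[(a, b)]
            if a == b:
                remaining[a] += 2 * k
            else:
                remaining[a] += k
                remaining[b] += k

    yield from rec(0, dict(allele_counts), {})


class _EnumerationOverflow(Exception):
    pass


def _hwe_enumeration(counts: GenotypeCounts, max_arrays: int) -> float:
    allele = _allele_counts(counts)
    lp_obs = _log_cond_prob(counts)
    total = 0.0
    p = 0.0
    for array in _enumerate_arrays(allele, max_arrays):
        lp = _log_cond_prob(array)
        prob = math.exp(lp)
        total += prob
        if lp <= lp_obs + _LOG_TOL:
            p += prob
    # normalise: guards against drift when the array space is large
    return min(1.0, p / total)


def _hwe_monte_carlo(
    counts: GenotypeCounts, mc_params: MCParams, seed: int | None
) -> tuple[float, float]:
    """Monte-Carlo exact HWE p-value from independent conditional-null draws.

    Randomly re-pairing the 2n observed gene copies induces exactly the
    Levene conditional distribution of genotype arrays given the allele
    counts, so each draw is an independent sample from the null. The
    p-value is the fraction of draws no more probable than the observed
    array; batch means give its standard error. ``dememorization`` is
    accepted for interface compatibility but unused (draws are
    independent, not a chain).
    """
    from scipy.special import gammaln

    alleles = sorted(_allele_counts(counts))
    k = len(alleles)
    index = {a: i for i, a in enumerate(alleles)}
    copies = np.concatenate(
        [np.repeat(index[a], c) for a, c in sorted(_allele_counts(counts).items())]
    )
    lp_obs = _log_cond_prob(counts)
    # comparable statistic per draw: het * ln 2 - sum lgamma(a_g + 1)
    obs_stat = sum(
        (c * _LOG2 if a != b else 0.0) - math.lgamma(c + 1) for (a, b), c in counts.items()
    )
    rng = np.random.default_rng(seed)
    batch_means = np.empty(mc_params.batches)
    n_codes = k * k
    for b in range(mc_params.batches):
        hits = 0
        for _ in range(mc_params.iterations):
            perm = rng.permutation(copies)
            a = perm[0::2]
            c = perm[1::2]
            lo = np.minimum(a, c)
            hi = np.maximum(a, c)
            cnt = np.bincount(lo * k + hi, minlength=n_codes)
            nz = cnt[cnt > 0]
            het = int((lo != hi).sum())
            stat = het * _LOG2 - float(gammaln(nz + 1).sum())
            if stat <= obs_stat + _LOG_TOL:
                hits += 1
        batch_means[b] = hits / mc_params.iterations
    p = float(batch_means.mean())
    se = float(batch_means.std(ddof=1) / math.sqrt(mc_params.batches))
    return p, se


def hwe_exact_test(
    counts: GenotypeCounts,
    method: str = "auto",
    mc_params: MCParams | None = None,
    seed: int | None = None,
    max_arrays: int = 1_000_000,
) -> HWEResult:
    """Exact probability test for Hardy-Weinberg proportions at one locus.

    ``method="auto"`` enumerates the array space when it holds at most
    ``max_arrays`` arrays, otherwise runs the Markov chain; ``"enumerate"``
    and ``"monte_carlo"`` force either route. A monomorphic locus returns
    p = 1 flagged untestable (only one array exists).
    """
    _validate_counts(counts)
    counts = {g: c for g, c in counts.items() if c > 0}
    n = sum(counts.values())
    if n < 2:
        raise ValidationError("HWE test needs at least 2 typed individuals")
    if len(_allele_counts(counts)) < 2:
        return HWEResult(1.0, "degenerate", testable=False)
    mc_params = mc_params or MCParams()
    if method not in ("auto", "enumerate", "monte_carlo"):
        raise ValidationError(f"unknown method {method!r}")
    k = len(_allele_counts(counts))
    m = k * (k + 1) // 2
    # compositions of n into m categories bound the array count from above;
    # in auto mode skip enumeration outright when the bound is hopeless
    array_bound = math.comb(n + m - 1, m - 1)
    if method == "enumerate" or (method == "auto" and array_bound <= max_arrays):
        try:
            p = _hwe_enumeration(counts, max_arrays)
            return HWEResult(p, "enumeration", testable=True)
        except _EnumerationOverflow:
            if method == "enumerate":
                raise ValidationError(
                    f"array space exceeds {max_arrays}; use method='monte_carlo'"
                ) from None
    p, se = _hwe_monte_carlo(counts, mc_params, seed)
    return HWEResult(p, "monte_carlo", testable=True, se=se)


# ---------------------------------------------------------------------------
# Genotypic linkage disequilibrium (Monte-Carlo exact test on the two-locus
# genotype contingency table).


def _log_table_prob(table: np.ndarray) -> float:
    """Log multivariate-hypergeometric probability of a contingency table given margins."""
    n = table.sum()
    lp = -math.lgamma(n + 1)
    for r in table.sum(axis=1):
        lp += math.lgamma(r + 1)
    for c in table.sum(axis=0):
        lp += math.lgamma(c + 1)
    lp -= sum(math.lgamma(v + 1) for v in table.ravel())
    return lp


def ld_genotypic_test(
    table: GenotypeTable,
    locus_a: str,
    locus_b: str,
    mc_params: MCParams | None = None,
    seed: int | None = None,
) -> LDResult:
    """Permutation exact test of genotypic independence between two loci.

    The statistic is the conditional probability of the two-locus genotype
    contingency table given its margins; one locus's genotypes are permuted
    among the shared typed individuals, and the p-value is the (add-one
    corrected) fraction of permutations no more probable than the observed
    table. Monomorphic loci return p = 1 flagged untestable.
    """
    mc_params = mc_params or MCParams()
    rng = np.random.default_rng(seed)
    ga, gb = [], []
    for ind in table.individuals:
        ca, cb = table.get(ind, locus_a), table.get(ind, locus_b)
        if ca is not None and cb is not None:
            ga.append(ca)
            gb.append(cb)
    if len(ga) < 2:
        raise ValidationError(f"loci {locus_a}/{locus_b}: fewer than 2 shared typed individuals")
    if len(set(ga)) < 2 or len(set(gb)) < 2:
        return LDResult(1.0, 0, testable=False)
    la = sorted(set(ga))
    lb = sorted(set(gb))
    ia = np.array([la.index(g) for g in ga])
    ib = np.array([lb.index(g) for g in gb])
    obs = np.zeros((len(la), len(lb)), dtype=np.int64)
    np.add.at(obs, (ia, ib), 1)
    lp_obs = _log_table_prob(obs)
    n_perm = mc_params.total
    hits = 0
    perm = ib.copy()
    for _ in range(n_perm):
        rng.shuffle(perm)
        t = np.zeros_like(obs)
        np.add.at(t, (ia, perm), 1)
        if _log_table_prob(t) <= lp_obs + _LOG_TOL:
            hits += 1
    return LDResult((hits + 1) / (n_perm + 1), n_perm, testable=True)


# ---------------------------------------------------------------------------
# Null-allele frequency estimators.


def _plain_het(counts: GenotypeCounts) -> tuple[float, float]:
    h_obs = observed_heterozygosity(counts)
    h_exp = expected_heterozygosity(counts, unbiased=False)
    return h_obs, h_exp


def _summers_amos(counts: GenotypeCounts, tol: float = 1e-10, max_iter: int = 100_000) -> float:
    """Iterative (EM) single-null-allele frequency estimate.

    Model: one non-amplifying allele of frequency r segregating at the
    locus; null heterozygotes appear homozygous, null homozygotes are
    unobserved. The E-step splits each apparent homozygote class between
    true homozygotes and null carriers (and imputes the unobserved null
    homozygotes); the M-step re-estimates allele frequencies from the
    completed gene counts. Iterated until the change in r is below ``tol``,
    this equates expected and observed homozygote excess under the model.
    """
    n = sum(counts.values())
    hom = Counter()
    het_copies = Counter()
    for (a, b), c in counts.items():
        if a == b:
            hom[a] += c
        else:
            het_copies[a] += c
            het_copies[b] += c
    allele = _allele_counts(counts)
    total = sum(allele.values())
    p = {a: c / total for a, c in allele.items()}
    r = 0.1
    for _ in range(max_iter):
        m = n * r * r / (1.0 - r * r) if r > 0 else 0.0  # imputed null homozygotes
        copies: dict[int, float] = dict(het_copies)
        null_copies = 2.0 * m
        for a, oh in hom.items():
            pa = p.get(a, 0.0)
            denom = pa + 2.0 * r
            w_null = (2.0 * r / denom) if denom > 0 else 0.0
            null_from_a = oh * w_null
            copies[a] = copies.get(a, 0.0) + 2.0 * oh * (1.0 - w_null) + null_from_a
            null_copies += null_from_a
        grand = 2.0 * (n + m)
        new_r = null_copies / grand
        p = {a: c / grand for a, c in copies.items()}
        if abs(new_r - r) < tol:
            return new_r
        r = new_r
    return r


def null_allele_frequency(counts: GenotypeCounts, estimator: str = "summers_amos") -> float:
    """Estimate the frequency of a non-amplifying (null) allele at one locus.

    ``chakraborty``: (He - Ho) / (He + Ho); ``brookfield1``: (He - Ho) /
    (1 + He); ``summers_amos``: iterative EM estimate. The closed forms use
    the plain expected heterozygosity 1 - sum p^2 so that all estimators
    return 0 when genotype frequencies sit exactly at Hardy-Weinberg
    proportions; negative closed-form estimates (heterozygote excess) are
    returned as-is.
    """
    _validate_counts(counts)
    counts = {g: c for g, c in counts.items() if c > 0}
    h_obs, h_exp = _plain_het(counts)
    if h_exp == 0.0:
        raise ValidationError("expected heterozygosity is 0 (monomorphic): null frequency undefined")
    if estimator == "chakraborty":
        return (h_exp - h_obs) / (h_exp + h_obs)
    if estimator == "brookfield1":
        return (h_exp - h_obs) / (1.0 + h_exp)
    if estimator == "summers_amos":
        return _summers_amos(counts)
    raise ValidationError(f"unknown estimator {estimator!r}")


# ---------------------------------------------------------------------------
# Panel-level reports.


def locus_qc(
    table: GenotypeTable,
    panel: LocusPanel | None = None,
    seed: int | None = None,
    mc_params: MCParams | None = None,
    hwe_method: str = "auto",
    max_arrays: int = 200_000,
) -> pd.DataFrame:
    """Per-locus QC report: n typed, H_obs, H_exp (unbiased), HWE p, null estimates."""
    panel = panel or default_panel()
    rows = []
    for i, locus in enumerate(l for l in panel.names if l in set(table.loci)):
        counts = genotype_counts(table, locus)
        n = sum(counts.values())
        if n == 0:
            warnings.warn(f"locus {locus}: no genotypes; skipped", stacklevel=2)
            continue
        locus_seed = None if seed is None else (seed + 1000 * i) % (2**31)
        hwe = hwe_exact_test(counts, hwe_method, mc_params, locus_seed, max_arrays=max_arrays)
        row = {
            "locus": locus,
            "n": n,
            "H_obs": observed_heterozygosity(counts),
            "H_exp": expected_heterozygosity(counts, unbiased=True),
            "hwe_p": hwe.p,
            "hwe_method": hwe.method,
        }
        for est in ("chakraborty", "brookfield1", "summers_amos"):
            try:
                row[f"null_{est}"] = null_allele_frequency(counts, est)
            except ValidationError:
                row[f"null_{est}"] = float("nan")
        rows.append(row)
    return pd.DataFrame(rows).set_index("locus")


def ld_pairwise(
    table: GenotypeTable,
    panel: LocusPanel | None = None,
    seed: int | None = None,
    mc_params: MCParams | None = None,
) -> pd.DataFrame:
    """Pairwise genotypic LD p-values over all locus pairs of the panel."""
    panel = panel or default_panel()
    loci = [l for l in panel.names if l in set(table.loci)]
    rows = []
    k = 0
    for i in range(len(loci)):
        for j in range(i + 1, len(loci)):
            pair_seed = None if seed is None else (seed + 7919 * k) % (2**31)
            res = ld_genotypic_test(table, loci[i], loci[j], mc_params, pair_seed)
            rows.append(
                {"locus_a": loci[i], "locus_b": loci[j], "p": res.p, "testable": res.testable}
            )
            k += 1
    return pd.DataFrame(rows)
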