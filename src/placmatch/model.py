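"""End-to-end study model: build from data, fit, inspect results.

``MHCSimilarityStudy`` holds validated inputs (genotypes, mare-foal pairs,
optionally a pedigree); ``fit()`` runs the full analysis — locus QC,
compatibility classification and tabulation, the RFM logistic model,
pairwise relatedness with its group comparison, and pedigree inbreeding
with its group comparison — and returns a ``StudyResults`` object carrying
every section, a ``summary()`` rendering shaped like the study's result
tables, and lossless JSON serialisation. Stochastic stages (HWE/LD Monte
Carlo) take the seed passed to ``fit``; re-running with identical inputs
and seed reproduces the report byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats as st

from . import __version__
from .compatibility import classify_pairs, tabulate_compatibility
from .errors import PlacmatchError, ValidationError
from .genotype_io import (
    GenotypeTable,
    LocusPanel,
    PairRecord,
    allele_frequencies,
    default_panel,
    read_genotypes,
    read_pairs,
    validate_pairs,
)
from .inference import (
    LogisticModelResult,
    clopper_pearson,
    fit_rfm_logistic,
    mann_whitney_u,
    students_t_test,
)
from .pedigree import Pedigree, inbreeding_report
from .popgen_qc import MCParams, ld_pairwise, locus_qc
from .relatedness import group_relatedness_summary, pair_relatedness

__all__ = ["MHCSimilarityStudy", "StudyResults", "run_full_analysis"]


def _stage(name: str):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PlacmatchError):
                raise PlacmatchError(f"stage '{name}' failed: {exc}") from exc
            if isinstance(exc, PlacmatchError) and not str(exc).startswith("stage"):
                raise PlacmatchError(f"stage '{name}': {exc}") from exc
            return False

    return _Ctx()


def _hash_table(table: GenotypeTable) -> str:
    h = hashlib.sha256()
    h.update(",".join(table.loci).encode())
    for ind in table.individuals:
        h.update(ind.encode())
        for locus in table.loci:
            h.update(str(table.get(ind, locus)).encode())
    return h.hexdigest()[:16]


class MHCSimilarityStudy:
    """Model of one mare-foal cohort: genotypes, pair outcomes, optional pedigree."""

    def __init__(
        self,
        genotypes: GenotypeTable,
        pairs: Sequence[PairRecord],
        panel: LocusPanel | None = None,
        pedigree: Pedigree | None = None,
    ):
        validate_pairs(pairs, genotypes)
        self.genotypes = genotypes
        self.pairs = list(pairs)
        self.panel = panel or default_panel()
        self.pedigree = pedigree

    @classmethod
    def from_files(
        cls,
        genotypes_path: str | Path,
        pairs_path: str | Path,
        pedigree_path: str | Path | None = None,
        format: str = "csv",
        panel: LocusPanel | None = None,
    ) -> "MHCSimilarityStudy":
        panel = panel or default_panel()
        table = read_genotypes(genotypes_path, format=format, panel=panel)
        pairs = read_pairs(pairs_path)
        pedigree = Pedigree.from_csv(pedigree_path) if pedigree_path else None
        return cls(table, pairs, panel, pedigree)

    def fit(
        self,
        seed: int | None = None,
        missing_policy: str = "ignore",
        mc_params: MCParams | None = None,
        run_ld: bool = True,
    ) -> "StudyResults":
        with _stage("qc"):
            qc = locus_qc(self.genotypes, self.panel, seed=seed, mc_params=mc_params)
            ld = (
                ld_pairwise(self.genotypes, self.panel, seed=seed, mc_params=mc_params)
                if run_ld
                else None
            )
        with _stage("classify"):
            calls = classify_pairs(self.genotypes, self.pairs, self.panel, missing_policy)
        with _stage("tabulate"):
            table2 = tabulate_compatibility(self.pairs, calls)
        with _stage("incidence"):
            n_rfm = sum(p.rfm for p in self.pairs)
            incidence = clopper_pearson(n_rfm, len(self.pairs))
        with _stage("logistic"):
            logistic = fit_rfm_logistic(calls)
        with _stage("relatedness"):
            freqs = allele_frequencies(self.genotypes)
            rxy = pair_relatedness(self.genotypes, self.pairs, freqs)
            rxy_summary = group_relatedness_summary(rxy)
            rfm_vals = rxy.loc[rxy["group"] == "RFM", "r_xy"].to_numpy()
            ctl_vals = rxy.loc[rxy["group"] == "control", "r_xy"].to_numpy()
            ttest = students_t_test(rfm_vals, ctl_vals)
            # document the t-test choice: normality of r_xy within groups
            shapiro = {
                grp: tuple(map(float, st.shapiro(vals)))
                for grp, vals in (("RFM", rfm_vals), ("control", ctl_vals))
                if len(vals) >= 3
            }
        inbreeding = None
        inbreeding_tests = None
        if self.pedigree is not None:
            with _stage("inbreeding"):
                inbreeding = inbreeding_report(self.pedigree, self.pairs)
                inbreeding_tests = {}
                for role in ("mare", "foal"):
                    sub = inbreeding[inbreeding["role"] == role]
                    f_rfm = sub.loc[sub["group"] == "RFM", "F"].to_numpy()
                    f_ctl = sub.loc[sub["group"] == "control", "F"].to_numpy()
                    mwu = mann_whitney_u(f_rfm, f_ctl)
                    inbreeding_tests[role] = {
                        "U": mwu.u,
                        "p": mwu.p,
                        "method": mwu.method,
                        "median_RFM": float(np.median(f_rfm)),
                        "iqr_RFM": float(np.subtract(*np.percentile(f_rfm, [75, 25]))),
                        "median_control": float(np.median(f_ctl)),
                        "iqr_control": float(np.subtract(*np.percentile(f_ctl, [75, 25]))),
                    }
        metadata = {
            "package_version": __version__,
            "seed": seed,
            "n_pairs": len(self.pairs),
            "genotypes_hash": _hash_table(self.genotypes),
            "missing_policy": missing_policy,
        }
        return StudyResults(
            incidence=incidence,
            locus_qc=qc,
            ld=ld,
            compatibility_calls=calls,
            compatibility_table=table2,
            logistic=logistic,
            relatedness=rxy,
            relatedness_summary=rxy_summary,
            relatedness_ttest=ttest,
            relatedness_normality=shapiro,
            inbreeding=inbreeding,
            inbreeding_tests=inbreeding_tests,
            metadata=metadata,
        )


@dataclass
class StudyResults:
    """Everything the fitted study produces, with rendering and serialisation."""

    incidence: object
    locus_qc: pd.DataFrame
    ld: pd.DataFrame | None
    compatibility_calls: pd.DataFrame
    compatibility_table: pd.DataFrame
    logistic: LogisticModelResult
    relatedness: pd.DataFrame
    relatedness_summary: pd.DataFrame
    relatedness_ttest: object
    relatedness_normality: dict
    inbreeding: pd.DataFrame | None
    inbreeding_tests: dict | None
    metadata: dict

    def summary(self) -> str:
        inc = self.incidence
        lines = [
            "MHC similarity and retained fetal membranes: study report",
            "=" * 60,
            "",
            f"Incidence of RFM: {inc.successes}/{inc.n} = {inc.point:.3f} "
            f"({inc.level:.0%} CI {inc.lower:.3f}-{inc.upper:.3f})",
            "",
            "Compatibility by group and MHC class (counts, % in brackets):",
        ]
        for (group, mhc_class), row in self.compatibility_table.iterrows():
            cells = "  ".join(
                f"{cat}: {row[f'n_{cat}']} ({row[f'pct_{cat}']})" for cat in ("MC", "FC", "MFC", "NC")
            )
            lines.append(f"  {group:8s} MHC {mhc_class:3s} (n={row['n']})  {cells}")
        lines += ["", self.logistic.summary(), "", "Pairwise relatedness r_xy by group:"]
        for group, row in self.relatedness_summary.iterrows():
            lines.append(f"  {group:8s} mean {row['mean']:.2f} +/- {row['sd']:.2f} (n={row['n']:.0f})")
        t = self.relatedness_ttest
        lines.append(f"  Student's t = {t.t:.2f} (df {t.df}, p = {t.p:.3f})")
        if self.inbreeding_tests is not None:
            lines += ["", "Inbreeding coefficients (median, IQR) and Mann-Whitney U:"]
            for role, res in self.inbreeding_tests.items():
                lines.append(
                    f"  {role}s: RFM {res['median_RFM']:.3f} ({res['iqr_RFM']:.3f}) vs control "
                    f"{res['median_control']:.3f} ({res['iqr_control']:.3f}); "
                    f"U = {res['U']:.0f}, p = {res['p']:.3f}"
                )
        lines += ["", "Locus QC (HWE p, null-allele estimates):"]
        qc = self.locus_qc.reset_index()
        for _, row in qc.iterrows():
            lines.append(
                f"  {row['locus']:10s} n={row['n']:3.0f} Ho={row['H_obs']:.2f} "
                f"He={row['H_exp']:.2f} HWE p={row['hwe_p']:.4f} "
                f"null={row['null_summers_amos']:.3f}"
            )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        inc = self.incidence
        t = self.relatedness_ttest
        payload = {
            "metadata": self.metadata,
            "incidence": {
                "successes": inc.successes,
                "n": inc.n,
                "point": inc.point,
                "lower": inc.lower,
                "upper": inc.upper,
                "level": inc.level,
            },
            "locus_qc": self.locus_qc.reset_index().to_dict(orient="records"),
            "ld": None if self.ld is None else self.ld.to_dict(orient="records"),
            "compatibility_calls": self.compatibility_calls.to_dict(orient="records"),
            "compatibility_table": self.compatibility_table.reset_index().to_dict(
                orient="records"
            ),
            "logistic": {
                "terms": self.logistic.terms.reset_index(names="term").to_dict(orient="records"),
                "n": self.logistic.n,
                "deviance_model": self.logistic.deviance_model,
                "deviance_null": self.logistic.deviance_null,
                "df_residual": self.logistic.df_residual,
                "df_null": self.logistic.df_null,
                "aic": self.logistic.aic,
                "bic": self.logistic.bic,
                "lr_chi2": self.logistic.lr_chi2,
                "lr_p": self.logistic.lr_p,
                "mcfadden_r2": self.logistic.mcfadden_r2,
                "cox_snell_r2": self.logistic.cox_snell_r2,
                "nagelkerke_r2": self.logistic.nagelkerke_r2,
                "tjur_r": self.logistic.tjur_r,
            },
            "relatedness": self.relatedness.to_dict(orient="records"),
            "relatedness_summary": self.relatedness_summary.reset_index().to_dict(
                orient="records"
            ),
            "relatedness_ttest": {"t": t.t, "df": t.df, "p": t.p},
            "relatedness_normality": self.relatedness_normality,
            "inbreeding": None
            if self.inbreeding is None
            else self.inbreeding.to_dict(orient="records"),
            "inbreeding_tests": self.inbreeding_tests,
        }
        return payload

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True, allow_nan=True) + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text


def run_full_analysis(
    genotypes: GenotypeTable,
    pairs: Sequence[PairRecord],
    pedigree: Pedigree | None = None,
    panel: LocusPanel | None = None,
    seed: int | None = None,
    missing_policy: str = "ignore",
    mc_params: MCParams | None = None,
    run_ld: bool = True,
) -> StudyResults:
    """Validate inputs, run every analysis stage, and return the study report."""
    study = MHCSimilarityStudy(genotypes, pairs, panel, pedigree)
    return study.fit(seed=seed, missing_policy=missing_policy, mc_params=mc_params, run_ld=run_ld)
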