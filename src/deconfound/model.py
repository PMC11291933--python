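"""Confounder-aware association model for one omics space and contrast.

:class:`ConfounderAnalysis` is the central modeling object: constructed
from a feature matrix and clinical metadata, its :meth:`fit` runs the
two-step framework --

1. a naive non-parametric screen of every (feature, variable) pair;
2. for each naively significant pair, iterative nested random-intercept
   model comparisons against every *other* naively significant variable
   for that feature, via two likelihood-ratio tests per candidate:

   * Test 1: ``rank(Y) ~ X + C + (1|subject)`` vs ``rank(Y) ~ X + (1|subject)``
     (does the candidate C explain variation beyond X?)
   * Test 2: ``rank(Y) ~ X + C + (1|subject)`` vs ``rank(Y) ~ C + (1|subject)``
     (does X retain explanatory power given C?)

   Only-Test-1-significant means the X association is statistically
   reducible to C ("confounded by C"); a significant Test 2 means it
   passes C; neither significant is "ambiguous".  LRT p-values are BH
   adjusted across all tests of the run before verdicts are drawn.

The result is one :class:`AssociationRecord` row per tested pair with a
final status: ``D`` (robust / deconfounded), ``confounded: [...]``,
``ambiguous``, or ``NS``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lmm import classify_two_tests, fit_lmm, lrt
from .screen import CovariateSet, contrast_label, contrast_mask, naive_screen
from .stats import bh_adjust, rank_transform

RECORD_COLUMNS = ["Y_dep.var", "X_ind.var", "XY_eff.size", "XY_p.adj",
                  "AssocStatus"]


def two_test_decision(y, disease, candidate, groups, alpha: float = 0.05):
    """One (feature, label, candidate) nested-model comparison.

    Fits ``rank(y) ~ D``, ``rank(y) ~ C`` and ``rank(y) ~ D + C`` (each
    with a per-subject random intercept) and returns
    ``(test1, test2, verdict)``: Test 1 compares the full model against
    the D-only model (does the candidate add explanatory power beyond
    the label?), Test 2 against the C-only model (does the label retain
    power given the candidate?).  The verdict uses raw p-values at
    ``alpha``; within :class:`ConfounderAnalysis` the same tests are
    instead BH-adjusted across the whole run before verdicts are drawn.
    """
    y = rank_transform(np.asarray(y, dtype=float))
    d = np.asarray(disease, dtype=float)
    c = np.asarray(candidate, dtype=float)
    full = fit_lmm(y, pd.DataFrame({"D": d, "C": c}), groups)
    m_d = fit_lmm(y, pd.DataFrame({"D": d}), groups)
    m_c = fit_lmm(y, pd.DataFrame({"C": c}), groups)
    t1, t2 = lrt(full, m_d), lrt(full, m_c)
    return t1, t2, classify_two_tests(t1.p, t2.p, alpha)


class ConfounderAnalysis:
    """Model object tying a feature table to clinical metadata.

    Parameters
    ----------
    features : DataFrame
        samples x features, log abundances (or any monotone scale; all
        statistics are rank-based).
    metadata : DataFrame
        indexed by sample id; must carry ``subject_id`` and ``status``
        columns plus the clinical covariates.
    contrast : str
        "status" (control vs mild) or "severity" (mild vs severe).
    covariates : CovariateSet, optional
        defaults to every metadata column besides the identifiers.
    """

    def __init__(self, features: pd.DataFrame, metadata: pd.DataFrame,
                 contrast: str = "severity",
                 covariates: CovariateSet | None = None,
                 space: str = "features"):
        missing = {"subject_id", "status"} - set(metadata.columns)
        if missing:
            raise ValueError(f"metadata lacks required columns {sorted(missing)}")
        common = features.index.intersection(metadata.index)
        if len(common) == 0:
            raise ValueError("features and metadata share no sample ids")
        self.features = features.loc[common]
        self.metadata = metadata.loc[common]
        self.contrast = contrast
        self.covariates = covariates or CovariateSet.from_metadata(self.metadata)
        self.space = space

    @classmethod
    def from_tables(cls, table, metadata: pd.DataFrame, **kwargs
                    ) -> "ConfounderAnalysis":
        """Build from a :class:`~deconfound.tables.FeatureTable` (log state)."""
        data = table.data
        if table.state == "concentration":
            data = np.log(data)
        elif table.state != "log":
            raise ValueError("expected a log or concentration table; run "
                             "filter_and_transform first")
        kwargs.setdefault("space", table.space)
        return cls(data, metadata, **kwargs)

    # -- fitting ----------------------------------------------------------

    def fit(self, fdr: float = 0.05, alpha_lrt: float = 0.05,
            collapse_subjects: bool = False) -> "ConfounderResults":
        naive = naive_screen(self.features, self.covariates, self.metadata,
                             self.contrast, collapse_subjects=collapse_subjects)
        mask = contrast_mask(self.metadata, self.contrast)
        sub_meta = self.metadata[mask]
        sub_feat = self.features[mask.to_numpy()]
        label = contrast_label(self.metadata, self.contrast)
        groups = sub_meta["subject_id"].to_numpy()

        xvalues = {self.contrast: label.to_numpy(dtype=float)}
        for name in self.covariates.kinds:
            xvalues[name] = self.covariates.values.loc[
                sub_meta.index, name].to_numpy(dtype=float)

        sig = naive[naive["testable"] & (naive["XY_p.adj"] <= fdr)]
        sig_by_feat: dict[str, list[str]] = {}
        for _, row in sig.iterrows():
            sig_by_feat.setdefault(row["Y_dep.var"], []).append(row["X_ind.var"])

        # fit all required models once per feature, then all LRTs
        diag_rows = []
        fits_cache: dict[tuple[str, frozenset], object] = {}

        def model_for(fid: str, terms: tuple[str, ...]):
            key = (fid, frozenset(terms))
            if key not in fits_cache:
                y = rank_transform(sub_feat[fid].to_numpy(dtype=float))
                X = pd.DataFrame({t: xvalues[t] for t in terms},
                                 index=sub_meta.index)
                fits_cache[key] = fit_lmm(y, X, groups)
            return fits_cache[key]

        for fid, sig_vars in sig_by_feat.items():
            for xvar in sig_vars:
                for cand in sig_vars:
                    if cand == xvar:
                        continue
                    full = model_for(fid, (xvar, cand))
                    m_x = model_for(fid, (xvar,))
                    m_c = model_for(fid, (cand,))
                    t1 = lrt(full, m_x)   # does cand add beyond xvar?
                    t2 = lrt(full, m_c)   # does xvar add beyond cand?
                    diag_rows.append({
                        "Y_dep.var": fid, "X_ind.var": xvar,
                        "candidate": cand,
                        "lrt1_stat": t1.statistic, "lrt1_p": t1.p,
                        "lrt2_stat": t2.statistic, "lrt2_p": t2.p,
                        "testable": t1.testable and t2.testable,
                        "singular_fit": any(getattr(m, "singular", False)
                                            for m in (full, m_x, m_c)),
                    })

        diagnostics = pd.DataFrame(
            diag_rows, columns=["Y_dep.var", "X_ind.var", "candidate",
                                "lrt1_stat", "lrt1_p", "lrt2_stat", "lrt2_p",
                                "testable", "singular_fit"])
        if len(diagnostics):
            # one BH family across every LRT performed in this run
            all_p = np.concatenate([diagnostics["lrt1_p"].to_numpy(),
                                    diagnostics["lrt2_p"].to_numpy()])
            adj = bh_adjust(all_p)
            diagnostics["lrt1_p.adj"] = adj[:len(diagnostics)]
            diagnostics["lrt2_p.adj"] = adj[len(diagnostics):]
            diagnostics["verdict"] = [
                classify_two_tests(r["lrt1_p.adj"], r["lrt2_p.adj"], alpha_lrt)
                for _, r in diagnostics.iterrows()]
        else:
            diagnostics["lrt1_p.adj"] = []
            diagnostics["lrt2_p.adj"] = []
            diagnostics["verdict"] = []

        records = self._assemble_records(naive, diagnostics, fdr)
        return ConfounderResults(self, naive, diagnostics, records,
                                 fdr=fdr, alpha_lrt=alpha_lrt)

    def _assemble_records(self, naive: pd.DataFrame,
                          diagnostics: pd.DataFrame,
                          fdr: float) -> pd.DataFrame:
        verd = {}
        for _, r in diagnostics.iterrows():
            verd.setdefault((r["Y_dep.var"], r["X_ind.var"]), []).append(
                (r["candidate"], r["verdict"]))
        rows = []
        for _, r in naive.iterrows():
            fid, xvar = r["Y_dep.var"], r["X_ind.var"]
            significant = bool(r["testable"]) and r["XY_p.adj"] <= fdr
            if not significant:
                status = "NS"
            else:
                verdicts = verd.get((fid, xvar), [])
                confounders = sorted(c for c, v in verdicts if v == "confounded")
                unresolved = [c for c, v in verdicts
                              if v in ("ambiguous", "untestable")]
                if confounders:
                    status = "confounded: " + ", ".join(confounders)
                elif unresolved:
                    status = "ambiguous"
                else:
                    status = "D"
            rows.append({"Y_dep.var": fid, "X_ind.var": xvar,
                         "XY_eff.size": r["XY_eff.size"],
                         "XY_p.adj": r["XY_p.adj"],
                         "AssocStatus": status})
        return pd.DataFrame(rows, columns=RECORD_COLUMNS)


@dataclass
class ConfounderResults:
    """Fit results: naive screen, LRT diagnostics, final records."""

    model: ConfounderAnalysis
    naive: pd.DataFrame
    diagnostics: pd.DataFrame
    records: pd.DataFrame
    fdr: float
    alpha_lrt: float

    @property
    def robust_features(self) -> list[str]:
        """Features robustly associated with the disease contrast."""
        rec = self.records
        hit = rec[(rec["X_ind.var"] == self.model.contrast)
                  & (rec["AssocStatus"] == "D")]
        return list(hit["Y_dep.var"])

    def status_counts(self) -> pd.Series:
        rec = self.records[self.records["X_ind.var"] == self.model.contrast]
        cls = rec["AssocStatus"].map(
            lambda s: "confounded" if s.startswith("confounded") else s)
        return cls.value_counts()

    def summary(self) -> str:
        rec = self.records
        n_pairs = len(rec)
        n_sig = int((rec["AssocStatus"] != "NS").sum())
        lines = [
            f"Confounder analysis: space={self.model.space!r} "
            f"contrast={self.model.contrast!r}",
            f"  samples: {len(self.model.features)}  "
            f"features: {self.model.features.shape[1]}  "
            f"pairs tested: {n_pairs}  significant: {n_sig}",
            f"  FDR={self.fdr}  LRT alpha={self.alpha_lrt} (BH-adjusted)",
            "  disease-contrast statuses:",
        ]
        for status, count in self.status_counts().items():
            lines.append(f"    {status:>12}: {count}")
        return "\n".join(lines)
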