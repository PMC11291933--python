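"""Cross-omics integration: robust disease-associated features of one
omics space are recycled as candidate explanatory variables when
re-testing robust features of the other spaces.

For every between-space pair of robust features, a naive Spearman
correlation (BH-adjusted across all candidate pairs) defines the edge;
each retained edge is then pushed through the same two-LRT nested-model
rule used for clinical covariates, in both orientations, with models
``rank(Y) ~ D``, ``rank(Y) ~ X_cross`` and ``rank(Y) ~ D + X_cross``
(each + (1|subject)).  When the reducibility verdict fires, the
feature's disease association is reclassified as confounded by the
cross-omics feature.  Edges are reported regardless of the verdict,
which is carried as an annotation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .lmm import classify_two_tests, fit_lmm, lrt
from .model import ConfounderResults
from .screen import contrast_label, contrast_mask
from .stats import bh_adjust, rank_transform, spearman_assoc

logger = logging.getLogger(__name__)

EDGE_COLUMNS = ["feature_a", "space_a", "feature_b", "space_b", "rho",
                "p_raw", "p_adj", "verdict_ab", "verdict_ba"]


def build_cross_candidates(robust_sets: dict[str, list[str]],
                           features_by_space: dict[str, pd.DataFrame],
                           ) -> list[tuple[str, str, str, str]]:
    """All between-space pairs of robust features.

    Returns tuples ``(space_a, feature_a, space_b, feature_b)`` with
    spaces in a fixed order so each unordered pair appears once.  Spaces
    with an empty robust set contribute nothing (logged); so do space
    pairs with no shared samples.
    """
    pairs = []
    for sa, sb in combinations(sorted(robust_sets), 2):
        fa, fb = robust_sets[sa], robust_sets[sb]
        if not fa or not fb:
            logger.warning("space %r has no robust features; no edges",
                           sa if not fa else sb)
            continue
        shared = features_by_space[sa].index.intersection(
            features_by_space[sb].index)
        if len(shared) == 0:
            logger.warning("spaces %r and %r share no samples; 0 testable "
                           "pairs", sa, sb)
            continue
        for a in fa:
            for b in fb:
                if a == b:  # self-pair guard
                    continue
                pairs.append((sa, a, sb, b))
    return pairs


class CrossOmicsIntegration:
    """Integration model over the per-space confounder-analysis results.

    Parameters
    ----------
    results_by_space : mapping of space -> ConfounderResults
        all fitted on the same contrast.
    features_by_space : mapping of space -> samples x features DataFrame
        the log-scale matrices the per-space analyses used.
    metadata : DataFrame indexed by sample id.
    """

    def __init__(self, results_by_space: dict[str, ConfounderResults],
                 features_by_space: dict[str, pd.DataFrame],
                 metadata: pd.DataFrame):
        contrasts = {r.model.contrast for r in results_by_space.values()}
        if len(contrasts) != 1:
            raise ValueError("per-space results must share one contrast")
        self.contrast = contrasts.pop()
        self.results_by_space = results_by_space
        self.features_by_space = features_by_space
        self.metadata = metadata

    def fit(self, fdr: float = 0.05, alpha_lrt: float = 0.05
            ) -> "CrossOmicsResults":
        robust_sets = {s: r.robust_features
                       for s, r in self.results_by_space.items()}
        pairs = build_cross_candidates(robust_sets, self.features_by_space)

        mask = contrast_mask(self.metadata, self.contrast)
        sub_meta = self.metadata[mask]
        label = contrast_label(self.metadata, self.contrast)

        rows = []
        for sa, a, sb, b in pairs:
            fa = self.features_by_space[sa]
            fb = self.features_by_space[sb]
            shared = fa.index.intersection(fb.index).intersection(sub_meta.index)
            if len(shared) < 3:
                continue
            rho, p = spearman_assoc(fa.loc[shared, a], fb.loc[shared, b])
            rows.append({"feature_a": a, "space_a": sa, "feature_b": b,
                         "space_b": sb, "rho": rho, "p_raw": p,
                         "_samples": shared})
        edges = pd.DataFrame(rows)
        if len(edges):
            edges["p_adj"] = bh_adjust(edges["p_raw"].to_numpy())
        else:
            edges = pd.DataFrame(columns=EDGE_COLUMNS + ["_samples"])
        retained = edges[edges["p_adj"] <= fdr].copy()

        # two-test re-modeling of each retained edge, both orientations;
        # the disease-only model for a feature is shared across its edges
        diag_rows = []
        fit_cache: dict[tuple, object] = {}

        def cached_fit(key, y, X, groups):
            if key not in fit_cache:
                fit_cache[key] = fit_lmm(y, X, groups)
            return fit_cache[key]

        for idx, e in retained.iterrows():
            shared = e["_samples"]
            d = label.loc[shared].to_numpy()
            groups = sub_meta.loc[shared, "subject_id"].to_numpy()
            skey = tuple(shared)
            for (ys, yf, xs, xf) in [
                    (e["space_b"], e["feature_b"], e["space_a"], e["feature_a"]),
                    (e["space_a"], e["feature_a"], e["space_b"], e["feature_b"])]:
                y = rank_transform(
                    self.features_by_space[ys].loc[shared, yf].to_numpy())
                xc = self.features_by_space[xs].loc[shared, xf].to_numpy()
                full = cached_fit((skey, ys, yf, xs, xf, "full"), y,
                                  pd.DataFrame({self.contrast: d, xf: xc}),
                                  groups)
                m_d = cached_fit((skey, ys, yf, "d"), y,
                                 pd.DataFrame({self.contrast: d}), groups)
                m_c = cached_fit((skey, ys, yf, xs, xf, "c"), y,
                                 pd.DataFrame({xf: xc}), groups)
                t1, t2 = lrt(full, m_d), lrt(full, m_c)
                diag_rows.append({"edge": idx, "Y_dep.var": yf,
                                  "Y_space": ys, "X_cross": xf,
                                  "X_space": xs,
                                  "lrt1_p": t1.p, "lrt2_p": t2.p})
        diagnostics = pd.DataFrame(
            diag_rows, columns=["edge", "Y_dep.var", "Y_space", "X_cross",
                                "X_space", "lrt1_p", "lrt2_p"])
        if len(diagnostics):
            all_p = np.concatenate([diagnostics["lrt1_p"],
                                    diagnostics["lrt2_p"]])
            adj = bh_adjust(all_p)
            diagnostics["lrt1_p.adj"] = adj[:len(diagnostics)]
            diagnostics["lrt2_p.adj"] = adj[len(diagnostics):]
            diagnostics["verdict"] = [
                classify_two_tests(r["lrt1_p.adj"], r["lrt2_p.adj"], alpha_lrt)
                for _, r in diagnostics.iterrows()]
        else:
            for col in ("lrt1_p.adj", "lrt2_p.adj", "verdict"):
                diagnostics[col] = []

        verdict_ab = {}
        verdict_ba = {}
        for _, r in diagnostics.iterrows():
            # orientation a->b: feature_a explains feature_b
            if r["Y_space"] == edges.loc[r["edge"], "space_b"]:
                verdict_ab[r["edge"]] = r["verdict"]
            else:
                verdict_ba[r["edge"]] = r["verdict"]
        retained["verdict_ab"] = [verdict_ab.get(i, "ambiguous")
                                  for i in retained.index]
        retained["verdict_ba"] = [verdict_ba.get(i, "ambiguous")
                                  for i in retained.index]
        retained = retained.drop(columns=["_samples"])[EDGE_COLUMNS]

        updated = self._update_records(diagnostics)
        return CrossOmicsResults(self, retained.reset_index(drop=True),
                                 diagnostics, updated, fdr=fdr,
                                 alpha_lrt=alpha_lrt)

    def _update_records(self, diagnostics: pd.DataFrame
                        ) -> dict[str, pd.DataFrame]:
        """Fold reducibility verdicts back into the disease-association
        records of each space."""
        reducible: dict[tuple[str, str], list[str]] = {}
        for _, r in diagnostics.iterrows():
            if r["verdict"] == "confounded":
                reducible.setdefault((r["Y_space"], r["Y_dep.var"]),
                                     []).append(r["X_cross"])
        updated = {}
        for space, res in self.results_by_space.items():
            rec = res.records.copy()
            for i, row in rec.iterrows():
                if row["X_ind.var"] != self.contrast:
                    continue
                extra = reducible.get((space, row["Y_dep.var"]))
                if not extra:
                    continue
                status = row["AssocStatus"]
                if status.startswith("confounded: "):
                    existing = status[len("confounded: "):].split(", ")
                else:
                    existing = []
                merged = sorted(set(existing) | set(extra))
                rec.at[i, "AssocStatus"] = "confounded: " + ", ".join(merged)
            updated[space] = rec
        return updated


@dataclass
class CrossOmicsResults:
    model: CrossOmicsIntegration
    edges: pd.DataFrame
    diagnostics: pd.DataFrame
    updated_records: dict[str, pd.DataFrame]
    fdr: float
    alpha_lrt: float

    def summary(self) -> str:
        lines = [f"Cross-omics integration (contrast={self.model.contrast!r}): "
                 f"{len(self.edges)} edges retained at FDR <= {self.fdr}"]
        for (sa, sb), grp in self.edges.groupby(["space_a", "space_b"]):
            lines.append(f"  {sa} -- {sb}: {len(grp)} edges")
        return "\n".join(lines)


def summarize_association_classes(records_by_space: dict[str, pd.DataFrame],
                                  contrast: str) -> tuple[pd.DataFrame,
                                                          pd.Series]:
    """Stacked status summary per omics space plus a confounder tally.

    Returns ``(fractions, tally)``: fractions of the contrast's features
    in each status class per space (rows sum to 1), and a count of how
    often each variable appears as a named confounder.
    """
    frac_rows = {}
    tally: dict[str, int] = {}
    for space, rec in records_by_space.items():
        sub = rec[rec["X_ind.var"] == contrast]
        if len(sub) == 0:
            continue
        classes = sub["AssocStatus"].map(
            lambda s: "confounded" if s.startswith("confounded") else
            ("robust" if s == "D" else s))
        frac_rows[space] = classes.value_counts(normalize=True)
        for status in sub["AssocStatus"]:
            if status.startswith("confounded: "):
                for var in status[len("confounded: "):].split(", "):
                    tally[var] = tally.get(var, 0) + 1
    fractions = pd.DataFrame(frac_rows).T.fillna(0.0)
    for col in ("robust", "confounded", "ambiguous", "NS"):
        if col not in fractions.columns:
            fractions[col] = 0.0
    fractions = fractions[["robust", "confounded", "ambiguous", "NS"]]
    return fractions, pd.Series(tally, dtype=int).sort_values(ascending=False)
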