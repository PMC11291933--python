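"""First-pass naive association screen.

For every (feature, clinical variable) pair within one disease contrast,
compute a standardized non-parametric effect size -- Cliff's delta with
a two-sided Mann-Whitney rank-sum p for binary variables, Spearman's rho
for continuous ones -- then Benjamini-Hochberg adjust across the screen.
The disease contrast label itself ("status" for control vs mild,
"severity" for mild vs severe) enters the screen as a binary variable.

Repeated samples per subject are used as-is here; within-subject
correlation is deferred to the mixed-model deconfounding stage.  An
optional collapse to per-subject means is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import (bh_adjust, cliffs_delta, is_testable, mann_whitney_p,
                    spearman_assoc)

CONTRASTS = {"status": ("control", "mild"), "severity": ("mild", "severe")}


@dataclass
class CovariateSet:
    """Per-sample clinical variables with declared types.

    ``kinds`` maps variable name -> "binary" | "continuous".  Variables
    not listed are inferred: a column whose observed values are a subset
    of {0, 1} is binary, anything else continuous.
    """

    values: pd.DataFrame
    kinds: dict[str, str]

    @classmethod
    def from_metadata(cls, metadata: pd.DataFrame,
                      exclude: tuple[str, ...] = ("subject_id", "timepoint",
                                                  "status")) -> "CovariateSet":
        cols = [c for c in metadata.columns if c not in exclude]
        values = metadata[cols].astype(float)
        kinds = {c: ("binary" if set(values[c].dropna().unique()) <= {0.0, 1.0}
                     else "continuous") for c in cols}
        return cls(values, kinds)


def contrast_mask(metadata: pd.DataFrame, contrast: str) -> pd.Series:
    """Boolean mask of samples belonging to the contrast's two groups."""
    if contrast not in CONTRASTS:
        raise ValueError(f"unknown contrast {contrast!r}; "
                         f"expected one of {sorted(CONTRASTS)}")
    lo, hi = CONTRASTS[contrast]
    return metadata["status"].isin([lo, hi])


def contrast_label(metadata: pd.DataFrame, contrast: str) -> pd.Series:
    """Binary disease label (0 = reference group, 1 = affected group)
    over the contrast subset."""
    lo, hi = CONTRASTS[contrast]
    sub = metadata[contrast_mask(metadata, contrast)]
    return (sub["status"] == hi).astype(float).rename(contrast)


def naive_screen(features: pd.DataFrame, covariates: CovariateSet,
                 metadata: pd.DataFrame, contrast: str,
                 collapse_subjects: bool = False,
                 min_nonzero: int = 3) -> pd.DataFrame:
    """Screen every testable (feature, variable) pair in one contrast.

    ``features`` is a samples x features matrix (log abundances or any
    monotone-equivalent scale).  Returns a long-format frame with
    columns Y_dep.var, X_ind.var, effect_type, XY_eff.size, p_raw,
    XY_p.adj, testable; BH adjustment spans all testable pairs of this
    screen (one omics space x one contrast).
    """
    if not features.index.equals(metadata.index):
        common = features.index.intersection(metadata.index)
        if len(common) == 0:
            raise ValueError("features and metadata share no samples")
        if len(common) < len(features.index) or len(common) < len(metadata.index):
            features = features.loc[common]
            metadata = metadata.loc[common]
        else:
            raise ValueError("features and metadata sample ids are misaligned")

    mask = contrast_mask(metadata, contrast)
    sub_meta = metadata[mask]
    sub_feat = features[mask.to_numpy()]
    label = contrast_label(metadata, contrast)
    cov_vals = covariates.values.loc[sub_meta.index]

    if collapse_subjects:
        subj = sub_meta["subject_id"].to_numpy()
        sub_feat = sub_feat.groupby(subj).mean()
        cov_vals = cov_vals.groupby(subj).mean().loc[sub_feat.index]
        status = sub_meta.groupby(subj)["status"].first().loc[sub_feat.index]
        label = (status == CONTRASTS[contrast][1]).astype(float)

    group1 = label.to_numpy() == 1.0
    group0 = ~group1

    xvars: dict[str, tuple[np.ndarray, str]] = {
        contrast: (label.to_numpy(), "binary")}
    for name, kind in covariates.kinds.items():
        xvars[name] = (cov_vals[name].to_numpy(dtype=float), kind)

    rows = []
    for fid in sub_feat.columns:
        y = sub_feat[fid].to_numpy(dtype=float)
        for xname, (x, kind) in xvars.items():
            testable = (xname == contrast and group0.sum() >= 1
                        and group1.sum() >= 1) or \
                (xname != contrast and is_testable(x, group0, group1,
                                                   min_nonzero))
            eff = p = float("nan")
            if testable:
                if kind == "binary":
                    hi, lo = y[x == 1.0], y[x != 1.0]
                    if len(hi) == 0 or len(lo) == 0 or np.ptp(y) == 0:
                        testable = False
                    else:
                        eff = cliffs_delta(hi, lo)
                        p = mann_whitney_p(hi, lo)
                else:
                    eff, p = spearman_assoc(x, y)
                    if np.isnan(eff):
                        testable = False
            rows.append({"Y_dep.var": fid, "X_ind.var": xname,
                         "effect_type": "cliffs_delta" if kind == "binary"
                         else "spearman_rho",
                         "XY_eff.size": eff, "p_raw": p,
                         "testable": testable})
    out = pd.DataFrame(rows)
    out["XY_p.adj"] = bh_adjust(out["p_raw"].to_numpy()) if len(out) else []
    out.attrs["contrast"] = contrast
    out.attrs["bh_family"] = "per screen (one omics space x one contrast)"
    return out[["Y_dep.var", "X_ind.var", "effect_type", "XY_eff.size",
                "p_raw", "XY_p.adj", "testable"]]
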