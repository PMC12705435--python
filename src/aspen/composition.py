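"""Age trends in cell-type composition.

Each donor's minor cell types are expressed as proportions of their parent
major type; proportions are correlated with donor age and BH correction is
applied among the minors that share a major type.  Donors lacking a major
type entirely contribute no observation for its minors (the denominator is
undefined, not zero).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .stats import bh_adjust, pearson_age_correlation


def minor_within_major_proportions(cells: pd.DataFrame) -> pd.DataFrame:
    """Per (donor, major, minor): cell count and proportion of the major total.

    Raises if any minor type maps to more than one major type.
    """
    mapping = cells.groupby("celltype_minor", observed=True)["celltype_major"].nunique()
    bad = mapping[mapping > 1]
    if len(bad):
        raise ValueError(f"minor types mapped to multiple majors: {list(bad.index)}")
    counts = (
        cells.groupby(["donor_id", "celltype_major", "celltype_minor"], observed=True)
        .size()
        .reset_index(name="n_cells")
    )
    totals = counts.groupby(["donor_id", "celltype_major"], observed=True)["n_cells"].transform("sum")
    counts["proportion"] = counts["n_cells"] / totals
    return counts


def composition_age_trend(
    composition: pd.DataFrame,
    donors: pd.DataFrame,
    method: str = "pearson",
) -> pd.DataFrame:
    """Correlate each minor type's proportion with age; BH within each major group.

    Minor types observed in fewer than 3 donors, or with constant
    proportions, are flagged not-testable and excluded from the correction.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    ages = donors["age"]
    rows = []
    for (major, minor), grp in composition.groupby(
        ["celltype_major", "celltype_minor"], observed=True
    ):
        props = grp.set_index("donor_id")["proportion"]
        common = [d for d in props.index if d in ages.index]
        x = props.loc[common].to_numpy(dtype=float)
        y = ages.loc[common].to_numpy(dtype=float)
        if method == "spearman":
            import scipy.stats

            x = scipy.stats.rankdata(x)
            y = scipy.stats.rankdata(y)
        res = pearson_age_correlation(x, y)
        rows.append(
            dict(celltype_major=major, celltype_minor=minor, n_donors=len(common),
                 r=res.r, p=res.p, testable=res.defined and len(common) >= 3)
        )
    out = pd.DataFrame(rows)
    out["padj"] = np.nan
    for major in out["celltype_major"].unique():
        mask = (out["celltype_major"] == major) & out["testable"]
        if mask.any():
            out.loc[mask, "padj"] = bh_adjust(out.loc[mask, "p"].to_numpy())
    return out
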