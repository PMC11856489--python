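"""Regressions of total mitogenome length on component lengths.

For each genome component (intronic, HEG, un_ORF, RNA, core genes,
intergenic) an ordinary least-squares fit of genome length on component
length yields R-squared (the squared Pearson correlation) and a
two-sided p-value from the slope t-statistic with n - 2 degrees of
freedom — the standard summary for asking which components drive genome
size variation across a cohort.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd
from scipy import stats


@dataclass
class RegressionResult:
    component: str
    n: int
    slope: float
    intercept: float
    r_squared: float
    p_value: float


def regress(pairs: list[tuple[float, float]], component: str = "") -> RegressionResult:
    """OLS of genome length (y) on component length (x).

    ``pairs`` holds (genome_length, component_length) tuples.  Zero
    variance in either variable yields an undefined (NaN) result.
    """
    if len(pairs) < 3:
        raise ValueError("need at least 3 genomes for a defined p-value")
    y = [float(p[0]) for p in pairs]
    x = [float(p[1]) for p in pairs]
    if len(set(x)) == 1 or len(set(y)) == 1:
        return RegressionResult(component, len(pairs), math.nan, math.nan,
                                math.nan, math.nan)
    fit = stats.linregress(x, y)
    return RegressionResult(component, len(pairs), fit.slope, fit.intercept,
                            fit.rvalue ** 2, fit.pvalue)


def regress_components(decompositions) -> pd.DataFrame:
    """Run the size regression for every component over a cohort of
    ComponentDecomposition results."""
    comps = ["core_pcg_exonic", "rna_region", "intronic", "un_orf",
             "intergenic", "heg_length"]
    rows = []
    for comp in comps:
        pairs = [(d.total, getattr(d, comp)) for d in decompositions]
        r = regress(pairs, comp)
        rows.append({"component": r.component, "n": r.n, "slope": r.slope,
                     "intercept": r.intercept, "r_squared": r.r_squared,
                     "p_value": r.p_value})
    return pd.DataFrame(rows, columns=["component", "n", "slope", "intercept",
                                       "r_squared", "p_value"])
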