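"""qPCR splicing-efficiency analysis for minor (U12-type) and major (U2)
introns.

Ct values are normalized against the geometric mean of three reference
genes (Gapdh, 18S, Lamin B); splicing efficiency is the ratio of normalized
spliced mRNA to unspliced pre-mRNA under the 2^(-dCt) quantification model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def normalize_ct(ct: float, reference_cts) -> float:
    """dCt = Ct - geometric mean of the reference Cts (cube root of product
    for the standard three references)."""
    refs = np.asarray(reference_cts, dtype=float)
    if ct <= 0 or np.any(refs <= 0):
        raise ValueError("Ct values must be positive")
    return float(ct - stats.gmean(refs))


def splicing_efficiency(delta_ct_spliced: float, delta_ct_unspliced: float,
                        amp_efficiency: float = 2.0) -> float:
    """Spliced/unspliced abundance ratio: E^(dCt_unspliced - dCt_spliced).

    amp_efficiency is the per-cycle amplification factor (2 = perfect
    doubling).
    """
    return float(amp_efficiency ** (delta_ct_unspliced - delta_ct_spliced))


@dataclass
class EfficiencyComparison:
    gene: str
    intron_class: str
    mean_a: float
    mean_b: float
    fold_change: float  # mean(B) / mean(A)
    p_value: float


def compare_efficiency(
    efficiencies_a, efficiencies_b, gene: str = "", intron_class: str = ""
) -> EfficiencyComparison:
    """Fold change (B over A) and two-sided two-sample t-test on replicate
    efficiencies; zero-variance identical groups report p = 1."""
    a = np.asarray(efficiencies_a, dtype=float)
    b = np.asarray(efficiencies_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 replicates per group")
    fold = float(b.mean() / a.mean())
    if np.allclose(a.std(), 0) and np.allclose(b.std(), 0):
        p = 1.0
    else:
        p = float(stats.ttest_ind(a, b).pvalue)
        if np.isnan(p):
            p = 1.0
    return EfficiencyComparison(gene, intron_class, float(a.mean()), float(b.mean()), fold, p)


def replicate_efficiencies(qpcr: pd.DataFrame, gene: str, intron_class: str,
                           cell_type: str, amp_efficiency: float = 2.0) -> np.ndarray:
    """Per-replicate splicing efficiencies for one gene/intron/cell type.

    Expects a tidy table with columns gene, intron_class, amplicon
    (spliced|unspliced), cell_type, replicate, ct and reference rows with
    gene == 'REF:<name>' matched by cell_type and replicate.
    """
    sub = qpcr[(qpcr.cell_type == cell_type)]
    refs = sub[sub.gene.str.startswith("REF:")]
    rows = sub[(sub.gene == gene) & (sub.intron_class == intron_class)]
    effs = []
    for rep in sorted(rows.replicate.unique()):
        ref_cts = refs[refs.replicate == rep].ct.to_numpy()
        r = rows[rows.replicate == rep]
        d_spliced = normalize_ct(float(r[r.amplicon == "spliced"].ct.iloc[0]), ref_cts)
        d_unspliced = normalize_ct(float(r[r.amplicon == "unspliced"].ct.iloc[0]), ref_cts)
        effs.append(splicing_efficiency(d_spliced, d_unspliced, amp_efficiency))
    return np.array(effs)


def efficiency_report(
    qpcr: pd.DataFrame, cell_a: str, cell_b: str, amp_efficiency: float = 2.0
) -> pd.DataFrame:
    """Fold change and p per gene x intron class between two cell types."""
    genes = sorted(g for g in qpcr.gene.unique() if not g.startswith("REF:"))
    rows = []
    for gene in genes:
        for ic in sorted(qpcr[qpcr.gene == gene].intron_class.unique()):
            a = replicate_efficiencies(qpcr, gene, ic, cell_a, amp_efficiency)
            b = replicate_efficiencies(qpcr, gene, ic, cell_b, amp_efficiency)
            cmp = compare_efficiency(a, b, gene, ic)
            rows.append(
                dict(
                    gene=gene,
                    intron_class=ic,
                    mean_efficiency_a=cmp.mean_a,
                    mean_efficiency_b=cmp.mean_b,
                    fold_change=cmp.fold_change,
                    p_value=cmp.p_value,
                )
            )
    return pd.DataFrame(rows)
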