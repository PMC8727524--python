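"""Relative qPCR quantification by the 2^−ΔΔCt method.

The pipeline follows the standard comparative-Ct procedure: for each
biological sample, the cycle threshold (Ct) of a target gene (the HCN
isoforms *Hcn1–4*) is normalized to the housekeeping gene *Rpl13a*
measured in the same sample (ΔCt), averaging technical replicates first;
ΔΔCt then references each sample's ΔCt to the mean ΔCt of the reference
(WT) group, and the fold change is 2^−ΔΔCt. The reference group's mean
log2 fold is zero by construction, so its geometric-mean fold is exactly 1.

The group comparison is a two-sample t-test on the ΔCt values (folds are
log-normal, so testing on the Ct scale matches standard practice).

A seeded generator produces synthetic Ct tables with known true fold
changes for validation; its default truth (Hcn1 and Hcn4 reduced, Hcn2 and
Hcn3 unchanged) is illustrative only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GENES",
    "HOUSEKEEPING",
    "DEFAULT_TRUE_FOLDS",
    "FoldChangeResult",
    "validate_ct_table",
    "delta_ct",
    "fold_change",
    "generate_ct_table",
]

HOUSEKEEPING = "Rpl13a"
GENES = ("Hcn1", "Hcn2", "Hcn3", "Hcn4")

#: illustrative true fold changes for the synthetic generator (KO vs WT)
DEFAULT_TRUE_FOLDS = {"Hcn1": 0.4, "Hcn2": 1.0, "Hcn3": 1.0, "Hcn4": 0.35}

#: plausible WT baseline Ct per gene (cycles) for the generator
_BASELINE_CT = {
    "Hcn1": 24.0,
    "Hcn2": 26.0,
    "Hcn3": 30.0,
    "Hcn4": 27.0,
    HOUSEKEEPING: 18.0,
}

_REQUIRED_COLS = {"sample", "genotype", "gene", "replicate", "ct"}


@dataclass
class FoldChangeResult:
    """Per-gene relative-expression summary (reference group fold ≡ 1)."""

    gene: str
    delta_ct: pd.DataFrame        # per-sample ΔCt (sample, genotype, dct)
    delta_delta_ct: pd.Series     # per-sample ΔΔCt, indexed by sample
    fold: pd.Series               # per-sample 2^−ΔΔCt
    group_mean: dict[str, float]  # genotype -> mean fold
    group_sem: dict[str, float]   # genotype -> SEM of fold
    t_stat: float
    p_value: float


def validate_ct_table(table: pd.DataFrame) -> None:
    missing = _REQUIRED_COLS - set(table.columns)
    if missing:
        raise ValueError(f"Ct table lacks columns: {sorted(missing)}")
    if ((table["ct"] <= 0) | (table["ct"] >= 45)).any():
        raise ValueError("Ct values must lie in (0, 45) cycles")
    counts = table.groupby(["sample", "gene"]).size()
    if counts.nunique() != 1:
        raise ValueError("every (sample, gene) needs the same replicate count")
    for sample, grp in table.groupby("sample"):
        if HOUSEKEEPING not in set(grp["gene"]):
            raise ValueError(f"sample {sample!r} lacks housekeeping gene {HOUSEKEEPING}")


def delta_ct(table: pd.DataFrame) -> pd.DataFrame:
    """Per-sample ΔCt for every target gene.

    Technical replicates are averaged per (sample, gene) first; ΔCt is the
    target's mean Ct minus the housekeeping gene's mean Ct in the same
    sample. Returns columns (sample, genotype, gene, dct).
    """
    validate_ct_table(table)
    means = (
        table.groupby(["sample", "genotype", "gene"], as_index=False)["ct"]
        .mean()
    )
    hk = means[means["gene"] == HOUSEKEEPING].set_index("sample")["ct"]
    targets = means[means["gene"] != HOUSEKEEPING].copy()
    targets["dct"] = targets["ct"].to_numpy() - hk.loc[targets["sample"]].to_numpy()
    return targets[["sample", "genotype", "gene", "dct"]].reset_index(drop=True)


def fold_change(
    dcts: pd.DataFrame, reference_group: str = "WT"
) -> dict[str, FoldChangeResult]:
    """2^−ΔΔCt fold changes per gene, referenced to a genotype group.

    ΔΔCt(sample) = ΔCt(sample) − mean ΔCt(reference group); the group test
    is a pooled two-sample t-test on the ΔCt values.
    """
    groups = set(dcts["genotype"])
    if reference_group not in groups or len(groups) < 2:
        raise ValueError("need the reference group and at least one other group")
    out: dict[str, FoldChangeResult] = {}
    for gene, sub in dcts.groupby("gene"):
        ref_mask = sub["genotype"] == reference_group
        if ref_mask.sum() < 2 or (~ref_mask).sum() < 2:
            raise ValueError(f"{gene}: need n >= 2 per group")
        ref_mean = float(sub.loc[ref_mask, "dct"].mean())
        ddct = sub.set_index("sample")["dct"] - ref_mean
        fold = np.power(2.0, -ddct)
        gm, gs = {}, {}
        for gname, grp in sub.groupby("genotype"):
            f = fold.loc[grp["sample"]]
            gm[gname] = float(f.mean())
            gs[gname] = float(f.std(ddof=1) / math.sqrt(len(f)))
        a = sub.loc[~ref_mask, "dct"].to_numpy()
        b = sub.loc[ref_mask, "dct"].to_numpy()
        if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
            # degenerate zero-noise tables: p = 1 for equal means, else 0
            if a.mean() == b.mean():
                t, p = 0.0, 1.0
            else:
                t = math.inf if a.mean() > b.mean() else -math.inf
                p = 0.0
        else:
            t, p = stats.ttest_ind(a, b, equal_var=True)
        out[gene] = FoldChangeResult(
            gene=gene,
            delta_ct=sub.reset_index(drop=True),
            delta_delta_ct=ddct,
            fold=fold,
            group_mean=gm,
            group_sem=gs,
            t_stat=float(t),
            p_value=float(p),
        )
    return out


def generate_ct_table(
    true_folds: dict[str, float] | None = None,
    noise_sd: float = 0.15,
    n_bio: int = 3,
    n_tech: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic Ct table with known KO/WT fold changes.

    WT Ct values sit at a per-gene baseline plus Gaussian noise (SD in
    cycles); KO target genes are shifted by −log2(fold); the housekeeping
    gene is genotype-independent up to noise.
    """
    true_folds = dict(DEFAULT_TRUE_FOLDS if true_folds is None else true_folds)
    unknown = set(true_folds) - set(GENES)
    if unknown:
        raise ValueError(f"unknown genes in true_folds: {sorted(unknown)}")
    if any(f <= 0 for f in true_folds.values()):
        raise ValueError("fold changes must be > 0")
    rng = np.random.default_rng(seed)
    rows = []
    for genotype in ("WT", "KO"):
        for b in range(n_bio):
            sample = f"{genotype}{b + 1}"
            for gene in (*GENES, HOUSEKEEPING):
                base = _BASELINE_CT[gene]
                if genotype == "KO" and gene in true_folds:
                    base = base - math.log2(true_folds[gene])
                for r in range(n_tech):
                    ct = base + rng.normal(0.0, noise_sd) if noise_sd > 0 else base
                    rows.append(
                        {
                            "sample": sample,
                            "genotype": genotype,
                            "gene": gene,
                            "replicate": r + 1,
                            "ct": ct,
                        }
                    )
    return pd.DataFrame(rows)
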