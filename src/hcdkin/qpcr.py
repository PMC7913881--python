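"""Relative RNA quantification from qPCR threshold cycles.

Amounts are expressed relative to a reference gene (16S rRNA by
default): a gene amplifying ΔCt cycles later than the reference is
present at efficiency^(−ΔCt) of its level, so

    relative amount = efficiency ** (Ct_ref − Ct_gene)

with the amplification efficiency as fold-per-cycle (2.0 = perfect
doubling).  Fold changes between growth conditions are ratios of these
amounts against a baseline condition (glucose), equivalent to
efficiency^(−ΔΔCt) when computed on mean Ct values.  Replicates are
averaged on the Ct scale, which is geometric-mean averaging on the
amount scale; dispersion is reported as the SD of per-replicate
amounts.

Failed/undetermined amplification is encoded as a missing Ct (NaN), and
propagates to amount 0 with ``detected = False`` — not to an arbitrary
cycle-cap substitution.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "relative_amount",
    "summarize_replicates",
    "fold_change",
    "validate_ct_table",
]

REQUIRED_COLUMNS = ("gene", "condition", "replicate", "ct")


def _check_efficiency(efficiency: float) -> None:
    if not (1.0 < efficiency <= 2.0):
        raise ValueError(f"amplification efficiency must be in (1, 2], got {efficiency}")


def validate_ct_table(table: pd.DataFrame, reference_gene: str = "16S") -> pd.DataFrame:
    """Check a long-format Ct table (gene, condition, replicate, ct)."""
    missing = set(REQUIRED_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    ct = table["ct"]
    finite = ct.dropna()
    if np.isinf(finite).any():
        raise ValueError("Ct values must be finite or missing (NaN = undetermined)")
    if reference_gene not in set(table["gene"]):
        raise ValueError(f"reference gene {reference_gene!r} absent from table")
    ref = table[table["gene"] == reference_gene]
    for cond, grp in table.groupby("condition"):
        if ref[ref["condition"] == cond]["ct"].notna().sum() < 1:
            raise ValueError(f"no reference measurement for condition {cond!r}")
    return table


def relative_amount(ct_gene: float, ct_ref: float, efficiency: float = 2.0) -> float:
    """Amount of a gene's transcript relative to the reference gene."""
    _check_efficiency(efficiency)
    return float(efficiency ** (ct_ref - ct_gene))


def summarize_replicates(
    table: pd.DataFrame,
    reference_gene: str = "16S",
    efficiency: float = 2.0,
) -> pd.DataFrame:
    """Per gene x condition relative amounts with replicate dispersion.

    The mean amount uses replicate-mean Ct values for gene and reference
    (geometric-mean semantics on the amount scale).  ``amount_sd`` is
    the SD of per-replicate amounts (NaN for a single replicate, 0 for
    identical ones).  Genes with no detected amplification in a
    condition get amount 0 and ``detected = False``.
    """
    _check_efficiency(efficiency)
    validate_ct_table(table, reference_gene)
    ref_means = (
        table[table["gene"] == reference_gene]
        .groupby("condition")["ct"]
        .mean()
    )
    rows = []
    genes = [g for g in table["gene"].unique() if g != reference_gene]
    for (gene, cond), grp in table[table["gene"].isin(genes)].groupby(
        ["gene", "condition"], sort=False
    ):
        ct_ref = ref_means[cond]
        cts = grp["ct"]
        detected = cts.notna()
        if detected.sum() == 0:
            rows.append(
                {"gene": gene, "condition": cond, "amount": 0.0,
                 "amount_sd": np.nan, "n_replicates": len(grp), "detected": False}
            )
            continue
        mean_ct = cts[detected].mean()
        amount = efficiency ** (ct_ref - mean_ct)
        per_rep = efficiency ** (ct_ref - cts[detected].to_numpy())
        sd = float(np.std(per_rep, ddof=1)) if detected.sum() > 1 else np.nan
        rows.append(
            {"gene": gene, "condition": cond, "amount": float(amount),
             "amount_sd": sd, "n_replicates": len(grp), "detected": True}
        )
    return pd.DataFrame(rows)


def fold_change(
    table: pd.DataFrame,
    gene: str,
    condition: str,
    baseline: str = "glucose",
    reference_gene: str = "16S",
    efficiency: float = 2.0,
) -> float:
    """Induction of ``gene`` in ``condition`` relative to the baseline.

    Ratio of replicate-mean relative amounts (condition over baseline);
    on mean Ct values this equals efficiency^(−ΔΔCt).  Raises if the
    baseline is absent; returns inf if the gene is undetected at
    baseline but detected in the condition, 0 if undetected in the
    condition.
    """
    summary = summarize_replicates(table, reference_gene, efficiency)
    summary = summary.set_index(["gene", "condition"])
    for cond in (baseline, condition):
        if (gene, cond) not in summary.index:
            raise ValueError(f"no data for gene {gene!r} in condition {cond!r}")
    base = summary.loc[(gene, baseline)]
    cur = summary.loc[(gene, condition)]
    if not cur["detected"]:
        return 0.0
    if not base["detected"] or base["amount"] == 0:
        return float("inf")
    return float(cur["amount"] / base["amount"])
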