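"""Genotype/outcome file IO, SNP quality-control filters, mean imputation,
and train/test splitting for real-data-style analyses.

File dialect: the genotype matrix is a tab-delimited text table with a
header row of variable IDs, one sample per row, entries in {0, 1, 2} or the
missing token "NA"; outcomes are a two-column tab-delimited file (time,
event) with a header.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .simdata import GenotypeMatrix, SurvivalOutcome

__all__ = [
    "QCReport",
    "read_genotypes",
    "write_genotypes",
    "read_outcome",
    "write_outcome",
    "qc_filter",
    "impute_mean",
    "split_train_test",
]

MISSING_TOKEN = "NA"


@dataclass
class QCReport:
    """Per-filter removal counts; filters apply sequentially (call rate,
    then HWE, then MAF) so no variable is double counted."""

    n_input: int
    n_removed_callrate: int
    n_removed_hwe: int
    n_removed_maf: int
    n_pass: int
    thresholds: dict

    def __post_init__(self):
        removed = (self.n_removed_callrate + self.n_removed_hwe
                   + self.n_removed_maf)
        assert self.n_pass == self.n_input - removed


def write_genotypes(X: GenotypeMatrix, path) -> None:
    ids = X.ids or [f"snp{j}" for j in range(X.p)]
    df = pd.DataFrame(X.values, columns=ids)
    # integer formatting when all non-missing entries are integral codes
    with np.errstate(invalid="ignore"):
        integral = bool(np.all(np.isnan(X.values)
                               | (X.values == np.floor(X.values))))
    df.to_csv(path, sep="\t", index=False, na_rep=MISSING_TOKEN,
              float_format="%.0f" if integral else "%.6g")


def read_genotypes(path) -> GenotypeMatrix:
    """Read a tab-delimited genotype table; missing entries become NaN."""
    try:
        df = pd.read_csv(path, sep="\t", na_values=[MISSING_TOKEN],
                         keep_default_na=False, dtype=float)
    except ValueError as exc:
        raise ValueError(f"malformed genotype file {path}: {exc}") from exc
    values = df.to_numpy(dtype=float)
    valid = np.isnan(values) | np.isin(values, (0.0, 1.0, 2.0))
    if not valid.all():
        bad_row = int(np.argwhere(~valid)[0, 0])
        raise ValueError(
            f"malformed genotype file {path}: non-genotype entry on data "
            f"line {bad_row + 1}")
    return GenotypeMatrix(values=values, ids=list(df.columns))


def write_outcome(outcome: SurvivalOutcome, path) -> None:
    pd.DataFrame({"time": outcome.time, "event": outcome.event}).to_csv(
        path, sep="\t", index=False)


def read_outcome(path) -> SurvivalOutcome:
    df = pd.read_csv(path, sep="\t")
    return SurvivalOutcome(time=df["time"].to_numpy(float),
                           event=df["event"].to_numpy(int))


def hwe_pvalue(column: np.ndarray) -> float:
    """One-degree chi-square Hardy-Weinberg goodness-of-fit p-value.

    Observed genotype counts are compared with expectations from the
    estimated allele frequency; monomorphic columns return p = 1.
    """
    col = column[~np.isnan(column)]
    n = col.size
    counts = np.array([(col == k).sum() for k in (0, 1, 2)], dtype=float)
    q_hat = (counts[1] + 2 * counts[2]) / (2 * n)
    if q_hat in (0.0, 1.0):
        return 1.0
    expected = n * np.array([(1 - q_hat) ** 2, 2 * q_hat * (1 - q_hat),
                             q_hat**2])
    chi2 = float(np.sum((counts - expected) ** 2 / expected))
    return float(stats.chi2.sf(chi2, df=1))


def _column_maf(values: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore"):
        freq = np.nanmean(values, axis=0) / 2.0
    return np.minimum(freq, 1.0 - freq)


def qc_filter(
    X: GenotypeMatrix,
    call_rate_min: float = 0.99,
    hwe_p_min: float = 1e-8,
    maf_min: float = 0.05,
    exclude_ids: set | None = None,
) -> tuple[GenotypeMatrix, QCReport]:
    """Sequential variable-level QC: call rate, HWE, then MAF.

    ``exclude_ids`` optionally removes named variables first (e.g., a
    non-autosomal ID list); those count toward none of the three filters.
    """
    values = X.values
    ids = X.ids or [f"snp{j}" for j in range(X.p)]
    keep = np.ones(values.shape[1], dtype=bool)
    if exclude_ids:
        keep &= ~np.isin(ids, list(exclude_ids))
    n_input = int(keep.sum())

    call_rate = 1.0 - np.isnan(values).mean(axis=0)
    fail_cr = keep & (call_rate < call_rate_min)
    keep &= ~fail_cr

    fail_hwe = np.zeros_like(keep)
    for j in np.flatnonzero(keep):
        if hwe_pvalue(values[:, j]) < hwe_p_min:
            fail_hwe[j] = True
    keep &= ~fail_hwe

    maf = _column_maf(values)
    fail_maf = keep & (maf < maf_min)
    keep &= ~fail_maf

    kept = np.flatnonzero(keep)
    out = GenotypeMatrix(values=values[:, kept], maf=maf[kept],
                         ids=[ids[j] for j in kept])
    report = QCReport(
        n_input=n_input,
        n_removed_callrate=int(fail_cr.sum()),
        n_removed_hwe=int(fail_hwe.sum()),
        n_removed_maf=int(fail_maf.sum()),
        n_pass=int(keep.sum()),
        thresholds={"call_rate_min": call_rate_min, "hwe_p_min": hwe_p_min,
                    "maf_min": maf_min},
    )
    return out, report


def impute_mean(X: GenotypeMatrix) -> GenotypeMatrix:
    """Replace missing entries by the column mean of non-missing entries."""
    values = X.values.copy()
    missing = np.isnan(values)
    fully_missing = missing.all(axis=0)
    if fully_missing.any():
        j = int(np.flatnonzero(fully_missing)[0])
        name = X.ids[j] if X.ids else f"column {j}"
        raise ValueError(f"cannot impute fully missing variable {name}")
    if missing.any():
        col_means = np.nanmean(values, axis=0)
        values[missing] = np.broadcast_to(col_means, values.shape)[missing]
    return GenotypeMatrix(values=values, maf=X.maf, ids=X.ids)


def split_train_test(X: GenotypeMatrix, outcome: SurvivalOutcome,
                     ratio: float = 2 / 3, seed=0):
    """Seeded random train/test row partition with ceil(ratio*n) training rows.

    Returns ((X_train, y_train), (X_test, y_test)).  The ceiling convention
    sends 623 rows at ratio 2/3 to a 419/204 split.
    """
    if not (0 < ratio < 1):
        raise ValueError("ratio must lie strictly between 0 and 1")
    n = X.n
    n_train = int(np.ceil(ratio * n))
    perm = np.random.default_rng(seed).permutation(n)
    tr, te = np.sort(perm[:n_train]), np.sort(perm[n_train:])

    def take(rows):
        return (
            GenotypeMatrix(values=X.values[rows], maf=X.maf, ids=X.ids),
            SurvivalOutcome(time=outcome.time[rows], event=outcome.event[rows]),
        )

    return take(tr), take(te)
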