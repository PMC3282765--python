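"""Relative quantification of qPCR data (2^-ddCt) and microarray concordance.

Ct values are normalized against a reference gene (hrdB, SCO5820, in the
original assays): dCt = mean Ct(gene) - mean Ct(reference) per sample
(technical replicates averaged on the Ct scale first), ddCt is taken
relative to a calibrator sample (the wild type by default), and the fold
change is 2^-ddCt with log2fold = -ddCt.  Amplification efficiency is fixed
at 2 per the Livak assumption.

Concordance with the microarray contrasts is the squared Pearson
correlation between qPCR log2 fold changes and microarray Mc values, with
the ordinary least-squares line reported alongside.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

from .spot_io import InputError

__all__ = ["CtTable", "RelativeExpression", "ddct", "concordance", "read_ct_table"]

CT_COLUMNS = ["gene_id", "sample", "replicate", "ct"]


@dataclasses.dataclass
class CtTable:
    """Long-format Ct measurements.

    ``data`` columns: gene_id, sample, replicate, ct.  The reference gene
    must be measured in every sample; the calibrator is the baseline sample
    for ddCt (fold = 1 there by construction).
    """

    data: pd.DataFrame
    reference_gene: str
    calibrator_sample: str

    def validate(self) -> "CtTable":
        missing = [c for c in CT_COLUMNS if c not in self.data.columns]
        if missing:
            raise InputError(f"Ct table is missing columns: {missing}")
        if not np.isfinite(self.data["ct"].to_numpy(float)).all():
            raise InputError("Ct values must be finite")
        samples = set(self.data["sample"])
        if self.calibrator_sample not in samples:
            raise InputError(f"calibrator sample {self.calibrator_sample!r} absent")
        ref_samples = set(
            self.data.loc[self.data["gene_id"] == self.reference_gene, "sample"]
        )
        lacking = sorted(samples - ref_samples)
        if lacking:
            raise InputError(
                f"reference gene {self.reference_gene!r} missing in samples: {lacking}"
            )
        return self


@dataclasses.dataclass
class RelativeExpression:
    """Per gene x sample: dCt, ddCt, fold = 2^-ddCt, log2fold = -ddCt."""

    table: pd.DataFrame
    reference_gene: str
    calibrator_sample: str


def read_ct_table(path, reference_gene: str, calibrator_sample: str) -> CtTable:
    data = pd.read_csv(path, sep="\t", comment="#")
    return CtTable(data, reference_gene, calibrator_sample).validate()


def ddct(ct: CtTable) -> RelativeExpression:
    """Livak relative quantification.

    Technical replicates are averaged on the Ct scale; a per-sample plate
    offset cancels in dCt, and the calibrator sample has ddCt = 0, fold = 1
    exactly.
    """
    ct.validate()
    mean_ct = ct.data.groupby(["gene_id", "sample"], sort=False)["ct"].mean()
    ref = mean_ct.xs(ct.reference_gene, level="gene_id")
    dct = mean_ct - ref.reindex(mean_ct.index.get_level_values("sample")).to_numpy()
    dct_cal = dct.xs(ct.calibrator_sample, level="sample")
    missing_cal = set(dct.index.get_level_values("gene_id")) - set(dct_cal.index)
    if missing_cal:
        raise InputError(
            f"genes without calibrator measurements: {sorted(missing_cal)}"
        )
    ddct_vals = dct - dct_cal.reindex(
        dct.index.get_level_values("gene_id")
    ).to_numpy()
    out = pd.DataFrame(
        {
            "dCt": dct,
            "ddCt": ddct_vals,
            "fold": 2.0 ** (-ddct_vals),
            "log2fold": -ddct_vals,
        }
    ).reset_index()
    return RelativeExpression(
        table=out,
        reference_gene=ct.reference_gene,
        calibrator_sample=ct.calibrator_sample,
    )


def concordance(qpcr_log2, mc) -> tuple[float, float, float]:
    """(r^2, slope, intercept) of qPCR log2 fold change on microarray Mc.

    r^2 is the squared Pearson correlation; slope/intercept come from the
    OLS line of qpcr_log2 on mc.  Pairs with a missing member are dropped;
    zero variance in either vector yields NaN throughout.
    """
    x = np.asarray(mc, float)
    y = np.asarray(qpcr_log2, float)
    if x.shape != y.shape:
        raise InputError("paired vectors must have equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise InputError("concordance requires >= 3 paired points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan"), float("nan")
    res = stats.linregress(x, y)
    return float(res.rvalue**2), float(res.slope), float(res.intercept)
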