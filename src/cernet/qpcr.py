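"""Relative quantification for the qPCR validation assays.

Expression ratios use the comparative 2^-ddCt model with a fixed
amplification efficiency of 2.0 (no standard-curve correction); mtDNA
content per nucleus compares a mitochondrial amplicon (e.g. 16S rRNA)
against a single-copy nuclear gene (e.g. GAPDH) carried at
``nuclear_copies_per_diploid_genome`` copies per nucleus.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

CT_RANGE = (0.0, 45.0)


def _check_ct(*cts) -> None:
    for ct in cts:
        ct = float(ct)
        if not np.isfinite(ct) or not CT_RANGE[0] < ct < CT_RANGE[1]:
            raise ValidationError(f"Ct out of range {CT_RANGE}: {ct}")


def delta_delta_ct(
    ct_target_sample: float,
    ct_ref_sample: float,
    ct_target_calibrator: float,
    ct_ref_calibrator: float,
    efficiency: float = 2.0,
) -> float:
    """Fold change of the target in the sample relative to the calibrator.

    ddCt = (Ct_target - Ct_ref)_sample - (Ct_target - Ct_ref)_calibrator;
    returns efficiency**(-ddCt), i.e. 2^-ddCt at perfect efficiency.
    """
    _check_ct(ct_target_sample, ct_ref_sample, ct_target_calibrator, ct_ref_calibrator)
    ddct = (ct_target_sample - ct_ref_sample) - (ct_target_calibrator - ct_ref_calibrator)
    return float(efficiency ** (-ddct))


def mtdna_copies_per_nucleus(
    ct_mt: float,
    ct_nuc: float,
    nuclear_copies_per_diploid_genome: float = 2.0,
    efficiency: float = 2.0,
) -> float:
    """Mitochondrial genome copies per nucleus from comparative qPCR.

    copies = nuclear_copies * efficiency**(Ct_nuc - Ct_mt); equal Cts mean
    the mitochondrial amplicon is as abundant as the diploid nuclear locus.
    """
    _check_ct(ct_mt, ct_nuc)
    return float(nuclear_copies_per_diploid_genome * efficiency ** (ct_nuc - ct_mt))


# ---------------------------------------------------------------------------
# Ct tables
# ---------------------------------------------------------------------------

CT_COLUMNS = ("sample_id", "assay_id", "target", "ct", "replicate")


def read_ct_table(path) -> pd.DataFrame:
    """TSV with columns sample_id, assay_id, target (goi|reference), ct, replicate."""
    df = pd.read_csv(path, sep="\t")
    missing = set(CT_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: Ct table missing columns {sorted(missing)}")
    return validate_ct_table(df)


def validate_ct_table(df: pd.DataFrame) -> pd.DataFrame:
    bad = df[(df["ct"] <= CT_RANGE[0]) | (df["ct"] >= CT_RANGE[1]) | df["ct"].isna()]
    if len(bad):
        r = bad.iloc[0]
        raise ValidationError(
            f"Ct out of range for sample {r['sample_id']!r}, assay {r['assay_id']!r}: {r['ct']}"
        )
    targets = set(df["target"])
    if not targets <= {"goi", "reference"}:
        raise ValidationError(f"target must be 'goi' or 'reference', got {sorted(targets)}")
    have = df.groupby(["sample_id", "assay_id"])["target"].agg(set)
    incomplete = have[have.map(lambda s: s != {"goi", "reference"})]
    if len(incomplete):
        s, a = incomplete.index[0]
        raise ValidationError(f"sample {s!r}, assay {a!r} lacks goi or reference Ct")
    return df


def relative_expression(
    ct: pd.DataFrame, calibrator_sample: str, efficiency: float = 2.0
) -> pd.DataFrame:
    """Per-sample, per-assay 2^-ddCt fold changes against one calibrator.

    Technical replicates are averaged on the Ct scale first (geometric-mean
    behavior on the linear scale), so averaging commutes with the ratio.
    """
    ct = validate_ct_table(ct)
    mean_ct = ct.groupby(["sample_id", "assay_id", "target"])["ct"].mean().unstack("target")
    if calibrator_sample not in ct["sample_id"].to_numpy():
        raise ValidationError(f"calibrator sample {calibrator_sample!r} not in table")
    rows = []
    for (sample, assay), row in mean_ct.iterrows():
        cal = mean_ct.loc[(calibrator_sample, assay)]
        fold = delta_delta_ct(
            row["goi"], row["reference"], cal["goi"], cal["reference"], efficiency
        )
        rows.append(
            {
                "sample_id": sample,
                "assay_id": assay,
                "fold": fold,
                "log2_fold": float(np.log2(fold)),
            }
        )
    return pd.DataFrame(rows, columns=["sample_id", "assay_id", "fold", "log2_fold"])
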