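"""Machine-readable transcription of the published HCC field-synopsis rows.

The 31 variant rows of the published synopsis (pooled OR with 95% CI,
two-sided P, heterogeneity Ph and I-squared, three-letter Venice grade and
the strong/moderate/weak evidence label) are shipped verbatim as packaged
data.  The underlying per-study extraction tables were never deposited, so
these printed summary rows are the only reference surface: they anchor the
self-consistency checks (Wald p from OR/CI, replication letters from
I-squared, composite labels from grade strings).

Rows presented under a dominant or recessive model additionally carry the
allele-contrast columns (``allelic_*``).  The printed ethnicity and
evidence-label strings are preserved exactly (including case); use
``label_normalized`` for comparisons.  The ``frequency`` column is the
effect-allele frequency as printed (two decimals for additive rows, six for
dominant/recessive rows).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

_NUMERIC = ["k", "n_cases", "n_controls", "or", "ci_low", "ci_high", "p", "ph",
            "i2", "allelic_or", "allelic_ci_low", "allelic_ci_high",
            "allelic_p", "allelic_ph", "allelic_i2", "frequency"]


def published_synopsis() -> pd.DataFrame:
    """The 31 published synopsis rows as a DataFrame.

    String columns keep the printed text verbatim (``p_str``, ``ph_str``
    retain the printed p strings, where ``"0"`` means p < 0.0005); numeric
    convenience columns are parsed floats.  ``label_normalized`` is the
    lower-cased evidence label.
    """
    with resources.files("hccmeta.data").joinpath("published_synopsis.csv").open(
            encoding="utf-8") as fh:
        df = pd.read_csv(fh, dtype=str, keep_default_na=False)
    df["p_str"] = df["p"]
    df["ph_str"] = df["ph"]
    df["allelic_p_str"] = df["allelic_p"]
    for col in _NUMERIC:
        df[col] = pd.to_numeric(df[col].replace("", pd.NA))
    df["label_normalized"] = df["label"].str.lower()
    return df
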