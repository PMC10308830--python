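"""Packaged worked-example fixtures: the published summary-table counts
the analysis reproduces (count columns of the concentration table, the
inventory-overlap figure, and the screening arithmetic)."""

from importlib import resources

import pandas as pd

__all__ = ["table1_counts", "fig5_counts", "screening_counts"]


def _load(name: str) -> pd.DataFrame:
    with resources.files(__package__).joinpath(name).open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh, sep="\t", comment="#")


def table1_counts() -> pd.DataFrame:
    """Count columns of the published concentration summary table."""
    df = _load("table1_counts.tsv")
    return df.fillna({"casrn": ""})


def fig5_counts() -> pd.DataFrame:
    """Published inventory overlap counts and declared inventory sizes."""
    return _load("fig5_counts.tsv")


def screening_counts() -> dict[str, int]:
    """Published screening arithmetic (initial/excluded/final list sizes)."""
    df = _load("screening_counts.tsv")
    return dict(zip(df["quantity"], df["value"].astype(int)))
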