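"""Reading feature tables and metadata from TSV/CSV."""

from __future__ import annotations

import os

import pandas as pd

from .errors import ValidationError

__all__ = ["read_table", "read_metadata"]


def _sep_for(path) -> str:
    ext = os.path.splitext(str(path))[1].lower()
    return "," if ext == ".csv" else "\t"


def read_table(path, orientation: str = "samples") -> pd.DataFrame:
    """Read an abundance table; first column is the sample (or feature) id.

    ``orientation="samples"`` expects samples as rows and features as
    columns; ``"features"`` transposes a features-by-samples file.
    """
    if orientation not in ("samples", "features"):
        raise ValidationError("orientation must be 'samples' or 'features'")
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    if df.shape[1] == 0:
        raise ValidationError(f"no feature columns found in {path}")
    if orientation == "features":
        df = df.T
    df.index = df.index.map(lambda s: str(s).strip())
    df.columns = df.columns.map(lambda s: str(s).strip())
    return df


def read_metadata(path) -> pd.DataFrame:
    """Read a metadata table indexed by sample id."""
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    df.index = df.index.map(lambda s: str(s).strip())
    return df
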