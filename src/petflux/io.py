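"""Plain-text serialisation: curve, expression and result tables (TSV)."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .frames import Curve, FrameSchedule


def write_curve(curve: Curve, path, header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        curve.to_frame().to_csv(fh, sep="\t", index=False, lineterminator="\n")


def read_curve(path, injection_offset_s: float = 30.0) -> Curve:
    """Read a curve TSV (frame_index, duration_s, mid_time_min, concentration).

    The schedule is reconstructed from the durations; ``injection_offset_s``
    must match the acquisition (validated against the stored mid-times).
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    schedule = FrameSchedule(
        durations_s=df["duration_s"].to_numpy(dtype=float),
        injection_offset_s=injection_offset_s,
    )
    if not np.allclose(schedule.mid_times_min,
                       df["mid_time_min"].to_numpy(dtype=float), atol=1e-6):
        raise ValueError(
            f"{path}: stored mid-times are inconsistent with the durations "
            f"and injection offset {injection_offset_s} s"
        )
    return Curve(schedule=schedule,
                 values=df["concentration_kBq_per_mL"].to_numpy(dtype=float))


def write_table(df: pd.DataFrame, path, header_comment: str | None = None,
                index: bool = True) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep="\t", index=index, lineterminator="\n")


def read_table(path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)


def write_expression(expression: pd.DataFrame, path,
                     header_comment: str | None = None) -> None:
    """Genes as rows, patients as columns, log2 values."""
    write_table(expression, path, header_comment)


def read_expression(path) -> pd.DataFrame:
    return read_table(path, index_col=0)
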