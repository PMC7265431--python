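"""Peptide query parameters shared by extraction, dilution, requant and imaging."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["PeptideQuery", "read_queries", "write_queries"]


@dataclass
class PeptideQuery:
    """A library peptide: precursor, fragments and where to look for it.

    ``rt_half_width`` (s) and ``mz_half_width_ppm`` set the retention-time and
    mass half-widths of every extraction box built for this peptide.
    """

    identifier: str
    precursor_mz: float
    charge: int
    fragment_mzs: np.ndarray
    expected_rt: float
    rt_half_width: float = 30.0
    mz_half_width_ppm: float = 50.0

    def __post_init__(self):
        self.fragment_mzs = np.atleast_1d(np.asarray(self.fragment_mzs, dtype=np.float64))
        if self.fragment_mzs.size == 0:
            raise ValueError("fragment_mzs must be non-empty")
        if not (self.rt_half_width > 0 and self.mz_half_width_ppm > 0):
            raise ValueError("extraction half-widths must be positive")
        if self.charge < 1:
            raise ValueError("charge must be a positive integer")

    def mz_band(self, mz: float) -> tuple[float, float]:
        """Half-open ppm band around ``mz``."""
        half = mz * self.mz_half_width_ppm * 1e-6
        return mz - half, mz + half


def read_queries(path) -> list[PeptideQuery]:
    """Read a query CSV: id, precursor_mz, charge, fragment_mzs (';'-separated),
    expected_rt, with optional rt_half_width / mz_half_width_ppm columns."""
    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        kwargs = {}
        for opt in ("rt_half_width", "mz_half_width_ppm"):
            if opt in df.columns and not pd.isna(row[opt]):
                kwargs[opt] = float(row[opt])
        out.append(
            PeptideQuery(
                identifier=str(row["id"]),
                precursor_mz=float(row["precursor_mz"]),
                charge=int(row["charge"]),
                fragment_mzs=np.array(
                    [float(x) for x in str(row["fragment_mzs"]).split(";")]
                ),
                expected_rt=float(row["expected_rt"]),
                **kwargs,
            )
        )
    return out


def write_queries(queries: list[PeptideQuery], path) -> None:
    pd.DataFrame(
        {
            "id": [q.identifier for q in queries],
            "precursor_mz": [q.precursor_mz for q in queries],
            "charge": [q.charge for q in queries],
            "fragment_mzs": [
                ";".join(repr(float(m)) for m in q.fragment_mzs) for q in queries
            ],
            "expected_rt": [q.expected_rt for q in queries],
            "rt_half_width": [q.rt_half_width for q in queries],
            "mz_half_width_ppm": [q.mz_half_width_ppm for q in queries],
        }
    ).to_csv(path, index=False)
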