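"""Reading and writing the three-column experiment file dialect.

The dialect is a plain-text table with exactly three numeric columns per
data line -- time (s), center temperature (degC), measurement uncertainty
(1 when unknown) -- separated by whitespace and/or commas.  Blank lines and
lines starting with ``#`` are skipped.  The decimal separator is ``.``;
locale-style decimal commas are rejected (they change the column count),
not guessed.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np

from .inverse import ObservationSeries, to_dimensionless  # noqa: F401  (re-export)

_SPLIT = re.compile(r"[,\s]+")


def read_exp(path) -> ObservationSeries:
    """Parse an experiment file into an :class:`ObservationSeries`.

    Raises ``ValueError`` naming the offending line on a wrong column
    count, a non-numeric entry, or a nonpositive sigma.
    """
    path = Path(path)
    times, temps, sigmas = [], [], []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tokens = [tok for tok in _SPLIT.split(line) if tok]
            if len(tokens) != 3:
                raise ValueError(
                    f"{path.name}:{lineno}: expected 3 columns, got {len(tokens)}")
            try:
                t, temp, sig = (float(tok) for tok in tokens)
            except ValueError:
                raise ValueError(
                    f"{path.name}:{lineno}: non-numeric entry in {tokens}") from None
            if sig <= 0:
                raise ValueError(
                    f"{path.name}:{lineno}: sigma must be positive, got {sig}")
            times.append(t)
            temps.append(temp)
            sigmas.append(sig)
    if not times:
        raise ValueError(f"{path.name}: no data rows")
    return ObservationSeries(times=np.array(times), temps=np.array(temps),
                             sigmas=np.array(sigmas))


def write_exp(series: ObservationSeries, path, header: str | None = None) -> None:
    """Write a series in the three-column dialect at full float precision."""
    path = Path(path)
    with path.open("w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        for t, temp, sig in zip(series.times, series.temps, series.sigmas):
            fh.write(f"{float(t)!r} {float(temp)!r} {float(sig)!r}\n")


def write_unsteady(times, values, path) -> None:
    """Two-column (time, simulated value) compatibility export.

    Mirrors the side files an external optimizer coupled through the file
    system would consume; provided for cross-checking only.
    """
    path = Path(path)
    with path.open("w") as fh:
        for t, v in zip(np.asarray(times, float), np.asarray(values, float)):
            fh.write(f"{float(t)!r} {float(v)!r}\n")
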