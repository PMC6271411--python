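"""File formats: melting-curve TSV, salt-series TSV, two-record FASTA.

Melting-curve TSV layout::

    # ct_M=1e-05
    # salt_species=Na+
    # salt_conc_M=0.1
    # ethanol_M=0
    # label=GC duplex
    temperature_C\tabsorbance
    0.0\t0.74812
    ...

Leading ``#`` lines carry ``key=value`` metadata (``ct_M`` is mandatory),
followed by a header line and tab-separated data rows. Temperatures are °C
on disk and converted at this boundary. All files are UTF-8, '.' decimal,
full ``repr`` precision, so writer → reader round trips are lossless.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
import pandas as pd
from Bio import SeqIO

from .nn import DuplexSequence, validate_duplex
from .salt import SaltSeries
from .simulate import MeltingCurve, SolutionCondition

__all__ = [
    "read_melting_curve",
    "write_melting_curve",
    "read_salt_series",
    "write_salt_series",
    "read_duplex_fasta",
]

_CURVE_HEADER = ("temperature_C", "absorbance")


class FormatError(ValueError):
    """Malformed input file; the message names the offending line."""


def _parse_metadata(lines: list[str], path: str) -> tuple[dict[str, str], int]:
    meta: dict[str, str] = {}
    i = 0
    for i, line in enumerate(lines):
        if not line.startswith("#"):
            break
        body = line.lstrip("#").strip()
        if not body:
            continue
        if "=" not in body:
            raise FormatError(f"{path}:{i + 1}: metadata line without '=': {line!r}")
        key, _, value = body.partition("=")
        meta[key.strip()] = value.strip()
    else:
        i += 1
    return meta, i


def read_melting_curve(path: str | Path) -> MeltingCurve:
    """Read one melting curve from the metadata-headed TSV format."""
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    meta, start = _parse_metadata(lines, str(path))
    if "ct_M" not in meta:
        raise FormatError(f"{path}: missing required metadata key 'ct_M'")
    if start >= len(lines):
        raise FormatError(f"{path}: no data rows")
    header = tuple(lines[start].rstrip("\n").split("\t"))
    if header != _CURVE_HEADER:
        expected = "\t".join(_CURVE_HEADER)
        raise FormatError(f"{path}:{start + 1}: expected header {expected!r}")
    body = "\n".join(lines[start + 1 :])
    try:
        table = pd.read_csv(
            _io.StringIO(body), sep="\t", names=_CURVE_HEADER, dtype=float
        )
    except ValueError as exc:
        raise FormatError(f"{path}: malformed data rows: {exc}") from exc
    if table.isna().any().any():
        bad = int(table.isna().any(axis=1).idxmax()) + start + 2
        raise FormatError(f"{path}:{bad}: malformed data row")
    condition = SolutionCondition(
        salt_species=meta.get("salt_species", "Na+"),
        salt_conc_M=float(meta.get("salt_conc_M", 1.0)),
        ethanol_M=float(meta.get("ethanol_M", 0.0)),
    )
    try:
        return MeltingCurve(
            temperatures=table["temperature_C"].to_numpy(),
            absorbance=table["absorbance"].to_numpy(),
            Ct=float(meta["ct_M"]),
            condition=condition,
            label=meta.get("label", path.stem),
        )
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_melting_curve(curve: MeltingCurve, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(f"# ct_M={curve.Ct!r}\n")
        fh.write(f"# salt_species={curve.condition.salt_species}\n")
        fh.write(f"# salt_conc_M={curve.condition.salt_conc_M!r}\n")
        fh.write(f"# ethanol_M={curve.condition.ethanol_M!r}\n")
        if curve.label:
            fh.write(f"# label={curve.label}\n")
        fh.write("\t".join(_CURVE_HEADER) + "\n")
        for t, a in zip(curve.temperatures, curve.absorbance):
            fh.write(f"{float(t)!r}\t{float(a)!r}\n")


def read_salt_series(path: str | Path) -> SaltSeries:
    """Read a salt series TSV: metadata header + concentration_M/value rows."""
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    meta, start = _parse_metadata(lines, str(path))
    header = tuple(lines[start].rstrip("\n").split("\t")) if start < len(lines) else ()
    if header[:2] != ("concentration_M", "value"):
        raise FormatError(f"{path}:{start + 1}: expected 'concentration_M\\tvalue' header")
    points = []
    for ln, line in enumerate(lines[start + 1 :], start=start + 2):
        if not line.strip():
            continue
        cells = line.split("\t")
        try:
            points.append((float(cells[0]), float(cells[1])))
        except (IndexError, ValueError) as exc:
            raise FormatError(f"{path}:{ln}: malformed data row {line!r}") from exc
    return SaltSeries(
        species=meta.get("species", "Na+"),
        points=tuple(points),
        value_kind=meta.get("value_kind", "minus_dg37"),  # type: ignore[arg-type]
        solvent_tag=meta.get("solvent_tag", "aqueous"),
        label=meta.get("label", path.stem),
    )


def write_salt_series(series: SaltSeries, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(f"# species={series.species}\n")
        fh.write(f"# value_kind={series.value_kind}\n")
        fh.write(f"# solvent_tag={series.solvent_tag}\n")
        if series.label:
            fh.write(f"# label={series.label}\n")
        fh.write("concentration_M\tvalue\n")
        for c, v in series.points:
            fh.write(f"{float(c)!r}\t{float(v)!r}\n")


def read_duplex_fasta(path: str | Path) -> DuplexSequence:
    """Read a duplex from a two-record FASTA: top strand, then bottom strand.

    Both records are 5'→3'; the pair is validated for antiparallel
    complementarity over the {A,C,G,T,I,D} pair set.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 2:
        raise FormatError(
            f"{path}: expected exactly 2 FASTA records (top, bottom), got {len(records)}"
        )
    return validate_duplex(str(records[0].seq), str(records[1].seq))
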