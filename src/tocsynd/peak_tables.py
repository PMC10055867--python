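"""Cross-peak tables for 2D :sup:`1`H-:sup:`1`H TOCSY metabolic profiling.

A TOCSY cross peak is a point (F2, F1) in a two-dimensional proton NMR
spectrum; both coordinates are resonance frequencies in Hz at the
spectrometer frequency (600.13 MHz here).  A metabolite contributes one
cross peak per multiplet pair, so one metabolite label usually covers
several peaks.  Between samples a metabolite's peaks drift by tens of Hz
(pH and ionic-strength effects) and whole metabolites appear or
disappear as the cells differentiate — the absence marker ``NP``
("not present") is first-class here rather than a NaN, because metabolite
disappearance is part of the signal being studied.

This module holds the data model (:class:`CrossPeak`, :class:`PeakTable`,
:class:`LabeledPeakSet`), the bundled reference table of intracellular
metabolites detected in adipose-tissue-derived human mesenchymal stem
cells (four samples: undifferentiated controls at day 4 and day 14,
adipogenic and osteogenic differentiation at day 14), and plain-text I/O
for peak lists.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

__all__ = [
    "SPECTROMETER_MHZ",
    "SPECTRAL_WIDTH_PPM",
    "SPECTRAL_WIDTH_HZ",
    "SAMPLES",
    "CrossPeak",
    "PeakTableRow",
    "PeakTable",
    "LabeledPeakSet",
    "load_reference_table",
    "extract_sample",
    "novel_labels",
    "hz_to_ppm",
    "ppm_to_hz",
    "read_peak_set",
    "write_peak_set",
]

#: Proton resonance frequency of the spectrometer, MHz (B0 = 14.1 T).
SPECTROMETER_MHZ = 600.13

#: Spectral width of the acquisition in both dimensions, ppm.
SPECTRAL_WIDTH_PPM = 12.00

#: Spectral width in Hz: 12 ppm at 600.13 MHz.
SPECTRAL_WIDTH_HZ = SPECTRAL_WIDTH_PPM * SPECTROMETER_MHZ  # 7201.56

#: Sample identifiers, in acquisition order: control day 4, control
#: day 14, adipogenic day 14, osteogenic day 14.
SAMPLES = ("Ct d4", "Ct d14", "AT d14", "OS d14")

# fixture column prefixes, keyed by public sample id
_SAMPLE_COLUMNS = {
    "Ct d4": "ct_d4",
    "Ct d14": "ct_d14",
    "AT d14": "at_d14",
    "OS d14": "os_d14",
}

_FIXTURE_NAME = "reference_peaks.tsv"


@dataclass(frozen=True)
class CrossPeak:
    """One TOCSY cross peak: (F2, F1) in Hz plus its metabolite label."""

    f2: float
    f1: float
    metabolite: str
    sample: str = ""

    def __post_init__(self) -> None:
        if not self.metabolite:
            raise ValueError("cross peak requires a non-empty metabolite label")
        for name, v in (("f2", self.f2), ("f1", self.f1)):
            if not 0.0 <= v <= SPECTRAL_WIDTH_HZ:
                raise ValueError(
                    f"{name}={v} Hz outside the spectral window "
                    f"[0, {SPECTRAL_WIDTH_HZ}] Hz"
                )


@dataclass(frozen=True)
class PeakTableRow:
    """One row of the multi-sample reference table.

    ``entries`` maps each sample id to an ``(f2, f1)`` pair in Hz or to
    ``None`` when the peak is marked NP (not present) in that sample.
    """

    metabolite: str
    entries: dict[str, Optional[tuple[float, float]]]
    standard: tuple[float, float]


@dataclass
class PeakTable:
    """Multi-sample cross-peak table with explicit absence markers."""

    rows: list[PeakTableRow]
    samples: tuple[str, ...] = SAMPLES

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def metabolites(self) -> list[str]:
        """Distinct metabolite labels, in first-appearance order."""
        seen: dict[str, None] = {}
        for r in self.rows:
            seen.setdefault(r.metabolite, None)
        return list(seen)

    def present_count(self, sample: str) -> int:
        """Number of non-NP peaks recorded for *sample*."""
        _check_sample(sample, self.samples)
        return sum(1 for r in self.rows if r.entries[sample] is not None)


@dataclass
class LabeledPeakSet:
    """All observed (non-NP) peaks of one sample."""

    sample: str
    peaks: list[CrossPeak]

    def __len__(self) -> int:
        return len(self.peaks)

    @property
    def labels(self) -> set[str]:
        return {p.metabolite for p in self.peaks}

    def features(self):
        """(n, 2) float array of (f2, f1) in Hz, row order preserved."""
        import numpy as np

        return np.array(
            [[p.f2, p.f1] for p in self.peaks], dtype=float
        ).reshape(-1, 2)


def _check_sample(sample: str, valid: Sequence[str]) -> None:
    if sample not in valid:
        raise KeyError(
            f"unknown sample {sample!r}; valid identifiers: {', '.join(valid)}"
        )


def _parse_pair(
    row: dict[str, str], prefix: str, line_no: int
) -> Optional[tuple[float, float]]:
    a, b = row.get(f"{prefix}_f2"), row.get(f"{prefix}_f1")
    if a is None or b is None:
        raise ValueError(f"line {line_no}: missing columns for {prefix!r}")
    np_flags = (a == "NP", b == "NP")
    if all(np_flags):
        return None
    if any(np_flags):
        raise ValueError(
            f"line {line_no}: half-specified entry for {prefix!r} "
            f"(F2={a!r}, F1={b!r}); an entry is either NP or a complete pair"
        )
    try:
        return (float(a), float(b))
    except ValueError as exc:
        raise ValueError(
            f"line {line_no}: non-numeric frequency for {prefix!r}: {exc}"
        ) from None


def load_reference_table() -> PeakTable:
    """Load the bundled reference table of hMSC intracellular metabolites.

    The table has 85 cross-peak rows over 32 metabolites; each row
    carries an (F2, F1) pair in Hz — or the absence marker NP — for each
    of the four samples, plus the standard (literature) frequencies.
    """
    src = resources.files("tocsynd.data").joinpath(_FIXTURE_NAME)
    with src.open("r", encoding="utf-8") as fh:
        return _parse_reference(fh)


def _parse_reference(fh: Iterable[str]) -> PeakTable:
    reader = csv.DictReader(fh, delimiter="\t")
    rows: list[PeakTableRow] = []
    for line_no, raw in enumerate(reader, start=2):
        met = (raw.get("metabolite") or "").strip()
        if not met:
            raise ValueError(f"line {line_no}: empty metabolite label")
        entries = {
            sample: _parse_pair(raw, prefix, line_no)
            for sample, prefix in _SAMPLE_COLUMNS.items()
        }
        std = _parse_pair(raw, "std", line_no)
        if std is None:
            raise ValueError(f"line {line_no}: standard frequencies may not be NP")
        rows.append(PeakTableRow(metabolite=met, entries=entries, standard=std))
    return PeakTable(rows=rows)


def extract_sample(table: PeakTable, sample: str) -> LabeledPeakSet:
    """All peaks observed in *sample* (rows whose entry is not NP), in
    table order."""
    _check_sample(sample, table.samples)
    peaks = [
        CrossPeak(f2=e[0], f1=e[1], metabolite=r.metabolite, sample=sample)
        for r in table.rows
        if (e := r.entries[sample]) is not None
    ]
    return LabeledPeakSet(sample=sample, peaks=peaks)


def novel_labels(train: LabeledPeakSet, test: LabeledPeakSet) -> set[str]:
    """Metabolite labels present in *test* but absent from *train*.

    These are the labels an open-set classifier trained on *train*
    should reject as novel.
    """
    return test.labels - train.labels


def hz_to_ppm(f: float, spectrometer_mhz: float = SPECTROMETER_MHZ) -> float:
    """Convert a frequency offset in Hz to ppm (ppm = Hz / MHz)."""
    if spectrometer_mhz <= 0:
        raise ValueError("spectrometer frequency must be positive")
    return f / spectrometer_mhz


def ppm_to_hz(ppm: float, spectrometer_mhz: float = SPECTROMETER_MHZ) -> float:
    """Inverse of :func:`hz_to_ppm`."""
    if spectrometer_mhz <= 0:
        raise ValueError("spectrometer frequency must be positive")
    return ppm * spectrometer_mhz


# ---------------------------------------------------------------------------
# Peak-set I/O
#
# The csv/tsv dialect is the package's own round-trippable format
# (header ``metabolite,f2_hz,f1_hz``).  The topspin-peaklist dialect is a
# read-only importer for the plain-text 2D peak lists exported by Bruker
# TopSpin: comment lines start with '#', data lines are whitespace-
# separated ``number F2 F1 intensity`` (intensity ignored; frequencies in
# Hz or ppm depending on export settings).
# ---------------------------------------------------------------------------

_DIALECTS = ("csv", "tsv", "topspin-peaklist")


def read_peak_set(
    path: Union[str, Path],
    dialect: str = "csv",
    sample: str = "",
    frequency_unit: str = "hz",
    spectrometer_mhz: float = SPECTROMETER_MHZ,
) -> LabeledPeakSet:
    """Read a labeled peak set from a plain-text file.

    Parameters
    ----------
    dialect
        ``csv``/``tsv``: header ``metabolite,f2_hz,f1_hz``.
        ``topspin-peaklist``: Bruker TopSpin text export, read-only;
        peaks get placeholder labels ``peak_1``, ``peak_2``, ...
    frequency_unit
        ``hz`` or ``ppm`` (topspin dialect only); ppm values are
        converted with *spectrometer_mhz*.
    """
    path = Path(path)
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; choose from {_DIALECTS}")
    if dialect == "topspin-peaklist":
        return _read_topspin(path, sample, frequency_unit, spectrometer_mhz)
    delim = "," if dialect == "csv" else "\t"
    peaks: list[CrossPeak] = []
    with path.open("r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delim)
        required = {"metabolite", "f2_hz", "f1_hz"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ValueError(
                f"{path}: missing columns; expected header "
                "metabolite,f2_hz,f1_hz"
            )
        for line_no, row in enumerate(reader, start=2):
            try:
                f2, f1 = float(row["f2_hz"]), float(row["f1_hz"])
            except (TypeError, ValueError):
                raise ValueError(
                    f"{path}: line {line_no}: non-numeric frequency"
                ) from None
            peaks.append(
                CrossPeak(f2=f2, f1=f1, metabolite=row["metabolite"], sample=sample)
            )
    return LabeledPeakSet(sample=sample, peaks=peaks)


def _read_topspin(
    path: Path, sample: str, frequency_unit: str, spectrometer_mhz: float
) -> LabeledPeakSet:
    if frequency_unit not in ("hz", "ppm"):
        raise ValueError("frequency_unit must be 'hz' or 'ppm'")
    peaks: list[CrossPeak] = []
    with path.open("r", encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            fields = stripped.split()
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {line_no}: expected at least 3 columns "
                    "(number, F2, F1[, intensity])"
                )
            try:
                f2, f1 = float(fields[1]), float(fields[2])
            except ValueError:
                raise ValueError(
                    f"{path}: line {line_no}: non-numeric frequency"
                ) from None
            if frequency_unit == "ppm":
                f2 = ppm_to_hz(f2, spectrometer_mhz)
                f1 = ppm_to_hz(f1, spectrometer_mhz)
            peaks.append(
                CrossPeak(
                    f2=f2,
                    f1=f1,
                    metabolite=f"peak_{len(peaks) + 1}",
                    sample=sample,
                )
            )
    return LabeledPeakSet(sample=sample, peaks=peaks)


def write_peak_set(
    peak_set: LabeledPeakSet, path: Union[str, Path], dialect: str = "csv"
) -> None:
    """Write a peak set in the round-trippable csv/tsv dialect.

    Frequencies are written with :func:`repr` so that a write → read
    round trip reproduces them bit-exactly.
    """
    if dialect not in ("csv", "tsv"):
        raise ValueError("write supports only the 'csv' and 'tsv' dialects")
    delim = "," if dialect == "csv" else "\t"
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter=delim)
        writer.writerow(["metabolite", "f2_hz", "f1_hz"])
        for p in peak_set.peaks:
            writer.writerow([p.metabolite, repr(p.f2), repr(p.f1)])
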