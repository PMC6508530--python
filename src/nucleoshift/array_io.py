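"""Data model and text I/O for the TSS-window tiling design and probe signals.

The design tiles a ~3000-bp window around each gene's transcription start
site (TSS) with short oligo probes.  Two hybridization channels are carried
per genotype: the *nucleosomal* channel (log2 ratio of MNase-digested
mono-/dinucleosomal DNA over undigested DNA) and the *reference* channel
(undigested genomic DNA on its own scale), each with several replicate
pools.  Signals travel in a simple 9-column GFF dialect (see
``write_signal_gff``); coordinates are 1-based inclusive throughout, as in
GFF.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

NUCLEOSOMAL = "nucleosomal"
REFERENCE = "reference"
CHANNELS = (NUCLEOSOMAL, REFERENCE)


class GFFParseError(ValueError):
    """Malformed signal-GFF input; carries the 1-based line number."""

    def __init__(self, lineno: int, message: str):
        super().__init__(f"line {lineno}: {message}")
        self.lineno = lineno


class LayoutValidationError(ValueError):
    """A probe or window violates the tiling-design invariants."""


@dataclass(frozen=True)
class Probe:
    probe_id: str
    window_id: str
    start: int  # 1-based inclusive
    end: int

    def __post_init__(self):
        if self.end < self.start:
            raise LayoutValidationError(
                f"probe {self.probe_id}: end {self.end} < start {self.start}"
            )

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class Window:
    """One 3000-bp (by default) region around a gene TSS.

    ``tss_offset`` is the absolute base position of the TSS, which must lie
    inside [start, end].  Windows are drawn left-to-right in transcriptional
    direction; ``strand`` records the gene's genomic orientation.
    """

    window_id: str
    gene_id: str
    chrom: str
    start: int
    end: int
    tss_offset: int
    strand: str = "+"

    def __post_init__(self):
        if not (self.start <= self.tss_offset <= self.end):
            raise LayoutValidationError(
                f"window {self.window_id}: TSS {self.tss_offset} outside "
                f"[{self.start}, {self.end}]"
            )

    @property
    def span(self) -> int:
        return self.end - self.start + 1


@dataclass
class ProbeLayout:
    """The tiling design: windows and their probes, in a fixed global order.

    Probes are stored sorted by (window order, start); ``probe_index`` maps
    probe_id -> (window_id, ordinal within window).  ``step`` is the
    start-to-start tiling distance of the design (used as the default
    continuity gap by the region caller).
    """

    windows: list[Window]
    probes: list[Probe]
    step: int | None = None
    probe_index: dict[str, tuple[str, int]] = field(init=False, repr=False)
    _window_by_id: dict[str, Window] = field(init=False, repr=False)
    _window_probes: dict[str, list[int]] = field(init=False, repr=False)

    def __post_init__(self):
        self._window_by_id = {w.window_id: w for w in self.windows}
        if len(self._window_by_id) != len(self.windows):
            raise LayoutValidationError("duplicate window_id")
        self._window_probes = {w.window_id: [] for w in self.windows}
        self.probe_index = {}
        for i, p in enumerate(self.probes):
            w = self._window_by_id.get(p.window_id)
            if w is None:
                raise LayoutValidationError(
                    f"probe {p.probe_id} references unknown window {p.window_id}"
                )
            if p.start < w.start or p.end > w.end:
                raise LayoutValidationError(
                    f"probe {p.probe_id} [{p.start},{p.end}] outside window "
                    f"{w.window_id} [{w.start},{w.end}]"
                )
            ordinals = self._window_probes[p.window_id]
            if ordinals:
                prev = self.probes[ordinals[-1]]
                if p.start < prev.start or (p.start, p.end) == (prev.start, prev.end):
                    raise LayoutValidationError(
                        f"probes of window {p.window_id} must be sorted by "
                        f"start and non-identical (at {p.probe_id})"
                    )
            if p.probe_id in self.probe_index:
                raise LayoutValidationError(f"duplicate probe_id {p.probe_id}")
            self.probe_index[p.probe_id] = (p.window_id, len(ordinals))
            ordinals.append(i)
        if self.step is None and len(self.probes) > 1:
            diffs = [
                self.probes[j + 1].start - self.probes[j].start
                for wid, idx in self._window_probes.items()
                for j in idx[:-1]
            ]
            self.step = int(min(diffs)) if diffs else None

    @property
    def n_probes(self) -> int:
        return len(self.probes)

    @property
    def probe_ids(self) -> list[str]:
        return [p.probe_id for p in self.probes]

    def window(self, window_id: str) -> Window:
        return self._window_by_id[window_id]

    def window_probe_rows(self, window_id: str) -> list[int]:
        """Global row indices of a window's probes, in 5'->3' order."""
        return list(self._window_probes[window_id])

    def row_of(self, probe_id: str) -> int:
        wid, ordinal = self.probe_index[probe_id]
        return self._window_probes[wid][ordinal]


@dataclass
class SignalSet:
    """Per-probe x per-replicate signals for one genotype and channel.

    ``values`` is an (n_probes, n_replicates) float array aligned to the
    layout's global probe order; NaN marks a missing cell.  The nucleosomal
    channel holds log2(MNase/undigested); the reference channel holds the
    genotype's undigested gDNA signal on whatever scale the upstream
    normalization produced (recorded in ``metadata``).
    """

    genotype: str
    channel: str
    replicate_ids: list[str]
    probe_ids: list[str]
    values: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.channel not in CHANNELS:
            raise ValueError(f"channel must be one of {CHANNELS}, got {self.channel!r}")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.probe_ids), len(self.replicate_ids)):
            raise ValueError(
                f"values shape {self.values.shape} != "
                f"({len(self.probe_ids)}, {len(self.replicate_ids)})"
            )

    @property
    def n_replicates(self) -> int:
        return len(self.replicate_ids)

    def check_layout(self, layout: ProbeLayout) -> None:
        if self.probe_ids != layout.probe_ids:
            raise ValueError(
                f"SignalSet ({self.genotype}/{self.channel}) is not aligned "
                "to the layout's probe order"
            )

    def testable_rows(self, min_replicates: int = 2) -> np.ndarray:
        """Boolean mask of probes with enough non-missing replicates."""
        return np.sum(~np.isnan(self.values), axis=1) >= min_replicates


@dataclass
class NOLTrack:
    """Sequence-predicted nucleosome occupancy likelihood, per chromosome.

    Stored as sorted position/score arrays; ``values_at`` linearly
    interpolates between stored positions and refuses to extrapolate, so a
    query outside the covered span is a hard error rather than a silent 0.
    """

    data: dict[str, tuple[np.ndarray, np.ndarray]]

    def values_at(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        positions = np.asarray(positions, dtype=float)
        if chrom not in self.data:
            raise KeyError(f"NOL track has no chromosome {chrom!r}")
        pos, score = self.data[chrom]
        lo, hi = pos[0], pos[-1]
        bad = (positions < lo) | (positions > hi)
        if np.any(bad):
            miss = positions[bad]
            raise ValueError(
                f"NOL track on {chrom} covers [{lo:g}, {hi:g}] but was queried "
                f"at {miss.min():g}..{miss.max():g}"
            )
        return np.interp(positions, pos, score)


def average_profile(signals: SignalSet) -> np.ndarray:
    """Per-probe mean over non-missing replicates (NaN where none exist).

    This is the averaging used for plotted profiles: replicate pools are
    averaged arithmetically, probe by probe.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows -> NaN
        return np.nanmean(signals.values, axis=1)


# ---------------------------------------------------------------------------
# Signal GFF dialect
#
# chrom  source  probe_signal  start  end  score  .  .  attributes
# attributes: probe_id=...;window_id=...;replicate_id=...;genotype=...;channel=...
# ---------------------------------------------------------------------------

_HEADER = "##gff-version 3"


def _parse_attributes(text: str, lineno: int) -> dict[str, str]:
    out = {}
    for item in text.strip().split(";"):
        item = item.strip()
        if not item:
            continue
        if "=" not in item:
            raise GFFParseError(lineno, f"malformed attribute {item!r}")
        k, v = item.split("=", 1)
        out[k.strip()] = v.strip()
    return out


def write_signal_gff(signals: SignalSet, layout: ProbeLayout, path) -> None:
    """Write one feature line per (probe, non-missing replicate).

    Scores are written with ``repr`` so floats round-trip exactly.
    """
    signals.check_layout(layout)
    source = signals.metadata.get("source", "nucleoshift-sim")
    with open(path, "w") as fh:
        fh.write(_HEADER + "\n")
        for probe in layout.probes:
            w = layout.window(probe.window_id)
            row = layout.row_of(probe.probe_id)
            for j, rep in enumerate(signals.replicate_ids):
                v = signals.values[row, j]
                if np.isnan(v):
                    continue
                attrs = (
                    f"probe_id={probe.probe_id};window_id={probe.window_id};"
                    f"replicate_id={rep};genotype={signals.genotype};"
                    f"channel={signals.channel}"
                )
                fh.write(
                    f"{w.chrom}\t{source}\tprobe_signal\t{probe.start}\t"
                    f"{probe.end}\t{float(v)!r}\t.\t.\t{attrs}\n"
                )


def read_signal_gff(path, layout: ProbeLayout) -> SignalSet:
    """Read a signal GFF back into a SignalSet aligned to ``layout``.

    Unknown probe_ids are collected into ``metadata['unknown_probes']`` and
    reported with a warning; cells never seen stay NaN (missing).
    """
    probe_rows = {p.probe_id: layout.row_of(p.probe_id) for p in layout.probes}
    rep_cols: dict[str, int] = {}
    cells: list[tuple[int, int, float]] = []
    unknown: list[str] = []
    genotype = channel = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GFFParseError(lineno, f"expected 9 columns, got {len(fields)}")
            chrom, _src, _feat, start_s, end_s, score_s = fields[:6]
            attrs = _parse_attributes(fields[8], lineno)
            for key in ("probe_id", "replicate_id"):
                if key not in attrs:
                    raise GFFParseError(lineno, f"missing attribute {key}")
            try:
                start, end = int(start_s), int(end_s)
                score = float(score_s)
            except ValueError as exc:
                raise GFFParseError(lineno, str(exc)) from None
            pid = attrs["probe_id"]
            if pid not in probe_rows:
                unknown.append(pid)
                continue
            wid, _ = layout.probe_index[pid]
            w = layout.window(wid)
            if start < w.start or end > w.end:
                raise LayoutValidationError(
                    f"line {lineno}: probe {pid} coordinates [{start},{end}] "
                    f"outside window {wid} [{w.start},{w.end}]"
                )
            genotype = attrs.get("genotype", genotype)
            channel = attrs.get("channel", channel)
            rep = attrs["replicate_id"]
            if rep not in rep_cols:
                rep_cols[rep] = len(rep_cols)
            cells.append((probe_rows[pid], rep_cols[rep], score))
    replicate_ids = sorted(rep_cols, key=rep_cols.get)
    values = np.full((layout.n_probes, len(replicate_ids)), np.nan)
    for row, col, score in cells:
        values[row, col] = score
    if unknown:
        warnings.warn(
            f"{path}: {len(unknown)} record(s) with probe_ids not in the "
            f"layout were skipped (first: {unknown[0]})"
        )
    return SignalSet(
        genotype=genotype or "unknown",
        channel=channel or NUCLEOSOMAL,
        replicate_ids=replicate_ids,
        probe_ids=layout.probe_ids,
        values=values,
        metadata={"unknown_probes": unknown},
    )


# ---------------------------------------------------------------------------
# Layout files: BED-like windows table + probe GFF without scores
# ---------------------------------------------------------------------------


def write_layout(layout: ProbeLayout, windows_path, probes_path) -> None:
    with open(windows_path, "w") as fh:
        fh.write("#chrom\tstart\tend\twindow_id\tgene_id\ttss_offset\tstrand\n")
        for w in layout.windows:
            fh.write(
                f"{w.chrom}\t{w.start}\t{w.end}\t{w.window_id}\t{w.gene_id}\t"
                f"{w.tss_offset}\t{w.strand}\n"
            )
    with open(probes_path, "w") as fh:
        fh.write(_HEADER + "\n")
        for p in layout.probes:
            w = layout.window(p.window_id)
            fh.write(
                f"{w.chrom}\tnucleoshift\tprobe\t{p.start}\t{p.end}\t.\t.\t.\t"
                f"probe_id={p.probe_id};window_id={p.window_id}\n"
            )


def read_layout(windows_path, probes_path) -> ProbeLayout:
    windows = []
    with open(windows_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 7:
                raise GFFParseError(lineno, f"expected 7 columns, got {len(fields)}")
            chrom, start, end, wid, gid, tss, strand = fields
            windows.append(
                Window(wid, gid, chrom, int(start), int(end), int(tss), strand)
            )
    probes = []
    with open(probes_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GFFParseError(lineno, f"expected 9 columns, got {len(fields)}")
            attrs = _parse_attributes(fields[8], lineno)
            probes.append(
                Probe(attrs["probe_id"], attrs["window_id"], int(fields[3]), int(fields[4]))
            )
    return ProbeLayout(windows=windows, probes=probes)


# ---------------------------------------------------------------------------
# NOL track: two-column (position, score) with chromosome section headers
# ---------------------------------------------------------------------------


def write_nol_track(track: NOLTrack, path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(track.data):
            pos, score = track.data[chrom]
            fh.write(f"#chrom={chrom}\n")
            for p, s in zip(pos, score):
                fh.write(f"{int(p)}\t{float(s)!r}\n")


def read_nol_track(path) -> NOLTrack:
    data: dict[str, list[tuple[float, float]]] = {}
    chrom = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#chrom="):
                chrom = line.split("=", 1)[1]
                data.setdefault(chrom, [])
                continue
            if line.startswith("#"):
                continue
            if chrom is None:
                raise GFFParseError(lineno, "NOL data before any #chrom= header")
            p, s = line.split("\t")
            data[chrom].append((float(p), float(s)))
    out = {}
    for chrom, pairs in data.items():
        pairs.sort()
        pos = np.array([p for p, _ in pairs])
        score = np.array([s for _, s in pairs])
        out[chrom] = (pos, score)
    return NOLTrack(out)
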