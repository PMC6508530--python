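"""Synthetic experiments with recorded ground truth.

The generator emulates the study design end to end: ~400 TSS windows of
3000 bp tiled with 50-bp probes, positioned-nucleosome peak/valley
structure, three replicate pools per genotype, genotype-specific planted
gains/losses/shifts of positioned nucleosomes, haplotype-specific
polymorphic windows that perturb both channels, a sequence-favored NOL
track, and qPCR Ct tables.  Everything is a deterministic function of the
seed, and the planted truth is recorded so that caller output can be
scored against it.

Signal model
------------
Occupancy of a genotype at base x is a clamped sum of Gaussian nucleosomes,
``clamp(sum_i h_i * exp(-(x - c_i)^2 / (2 sd_i^2)), 0, 1)``.  The
nucleosomal-channel probe value is
``log2(mean_occupancy_over_probe * dynamic_range + floor) + noise``; the
reference channel is a flat baseline plus noise.  A planted polymorphism
shifts BOTH channels of the non-reference haplotype inside its interval
(mismatched probes hybridize less, regardless of channel); a planted NP
change perturbs occupancy and therefore only the nucleosomal channel.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .array_io import (
    NOLTrack,
    NUCLEOSOMAL,
    Probe,
    ProbeLayout,
    REFERENCE,
    SignalSet,
    Window,
)

# Signal-model constants: peak-scale factor and background floor chosen so a
# 2^-delta occupancy drop maps to ~ -delta log2 signal across the footprint.
DYNAMIC_RANGE = 4.0
FLOOR = 0.0625
REF_BASELINE = 0.0

NUCLEOSOME_SD = 30.0  # bp; ~150-bp footprint at +-2.5 sd
NUCLEOSOME_SPACING = 200  # bp between adjacent slot centers
SLOT_DROP_PROB = 0.25  # fraction of slots left empty (valleys)


def _rng(seed: int, *names: str) -> np.random.Generator:
    """Independent, reproducible stream keyed by seed plus string labels."""
    return np.random.default_rng(
        [int(seed) & 0x7FFFFFFF] + [zlib.crc32(n.encode()) for n in names]
    )


@dataclass(frozen=True)
class PlantedChange:
    window_id: str
    start: int
    end: int
    kind: str  # "gain" | "loss"
    delta: float  # effect size, log2 units
    shift_group: int | None = None  # links the loss+gain halves of a shift


@dataclass(frozen=True)
class PlantedPolymorphism:
    window_id: str
    start: int
    end: int
    effect: float  # log2 hybridization shift magnitude in the divergent haplotype


@dataclass
class SyntheticTruth:
    """Planted nucleosomes, NP changes and polymorphisms, plus noise model."""

    nucleosomes: dict[str, dict[str, list[tuple[float, float, float]]]]
    planted_changes: list[PlantedChange]
    planted_polymorphisms: list[PlantedPolymorphism]
    noise_sd: dict[str, float]
    seed: int
    reference_genotype: str
    dynamic_range: float = DYNAMIC_RANGE
    floor: float = FLOOR
    baseline: float = REF_BASELINE

    @property
    def genotypes(self) -> list[str]:
        return list(self.nucleosomes)

    def to_json(self, path) -> None:
        payload = {
            "nucleosomes": self.nucleosomes,
            "planted_changes": [asdict(c) for c in self.planted_changes],
            "planted_polymorphisms": [asdict(p) for p in self.planted_polymorphisms],
            "noise_sd": self.noise_sd,
            "seed": self.seed,
            "reference_genotype": self.reference_genotype,
            "dynamic_range": self.dynamic_range,
            "floor": self.floor,
            "baseline": self.baseline,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            nucleosomes={
                g: {w: [tuple(n) for n in nucs] for w, nucs in wins.items()}
                for g, wins in d["nucleosomes"].items()
            },
            planted_changes=[PlantedChange(**c) for c in d["planted_changes"]],
            planted_polymorphisms=[
                PlantedPolymorphism(**p) for p in d["planted_polymorphisms"]
            ],
            noise_sd=d["noise_sd"],
            seed=d["seed"],
            reference_genotype=d["reference_genotype"],
            dynamic_range=d["dynamic_range"],
            floor=d["floor"],
            baseline=d["baseline"],
        )


def simulate_layout(
    n_windows: int,
    span: int = 3000,
    probe_length: int = 50,
    step: int = 50,
    seed: int = 0,
    windows_per_chrom: int = 50,
    gap: int = 1000,
) -> ProbeLayout:
    """Fully tiled synthetic layout: ``n_windows`` TSS windows of ``span`` bp.

    Windows are laid out left to right on synthetic chromosomes
    (``windows_per_chrom`` each, separated by ``gap`` bp), TSS at the window
    center.  The structure is deterministic; ``seed`` is accepted for
    interface uniformity.
    """
    if n_windows <= 0 or span < probe_length or probe_length < 1 or step < 1:
        raise ValueError("non-positive or inconsistent layout arguments")
    windows: list[Window] = []
    probes: list[Probe] = []
    for i in range(n_windows):
        chrom = f"simchr{i // windows_per_chrom + 1}"
        slot = i % windows_per_chrom
        start = 1 + slot * (span + gap)
        end = start + span - 1
        wid = f"win{i:04d}"
        windows.append(
            Window(wid, f"gene{i:04d}", chrom, start, end, start + span // 2, "+")
        )
        k = 0
        pos = start
        while pos + probe_length - 1 <= end:
            probes.append(Probe(f"{wid}_p{k:03d}", wid, pos, pos + probe_length - 1))
            pos += step
            k += 1
    return ProbeLayout(windows=windows, probes=probes, step=step)


def make_truth(
    layout: ProbeLayout,
    wild_type: str = "WT",
    mutant: str = "mut",
    n_changes: int = 0,
    change_kinds: tuple[str, ...] = ("gain", "loss"),
    change_span: int = 200,
    delta: float = 1.0,
    n_polymorphic: int = 0,
    divergence: float = 3.0,
    polymorphic_span_frac: float = 0.8,
    noise_sd: float | dict[str, float] = 0.2,
    seed: int = 0,
    reference_genotype: str | None = None,
) -> SyntheticTruth:
    """Build a two-genotype truth with planted changes and polymorphisms.

    Base chromatin is shared: nucleosome slots every ``NUCLEOSOME_SPACING``
    bp (small jitter), a quarter left empty as valleys, heights U(0.5, 0.9).
    A *gain* empties a slot in both genotypes and adds a nucleosome of
    height ``(2^delta - 1) * 0.75`` (clipped to 1) to the mutant there; a
    *loss* multiplies the heights of mutant nucleosomes inside the interval
    by ``2^-delta``; a *shift* is a loss at one slot plus a gain at an
    adjacent empty slot, recorded as two linked intervals.  Polymorphic
    windows are disjoint from changed windows.
    """
    rng = _rng(seed, "truth")
    if isinstance(noise_sd, (int, float)):
        noise_sd = {NUCLEOSOMAL: float(noise_sd), REFERENCE: float(noise_sd)}
    for kind in change_kinds:
        if kind not in ("gain", "loss", "shift"):
            raise ValueError(f"unknown change kind {kind!r}")

    # base chromatin: per-window slots
    slots: dict[str, list[dict]] = {}
    for w in layout.windows:
        entries = []
        c = w.start + NUCLEOSOME_SPACING // 2
        while c <= w.end - NUCLEOSOME_SPACING // 4:
            entries.append(
                {
                    "center": float(c + rng.integers(-10, 11)),
                    "height": float(rng.uniform(0.5, 0.9)),
                    "kept": bool(rng.random() >= SLOT_DROP_PROB),
                }
            )
            c += NUCLEOSOME_SPACING
        if not any(e["kept"] for e in entries):
            entries[len(entries) // 2]["kept"] = True
        slots[w.window_id] = entries

    window_ids = [w.window_id for w in layout.windows]
    n_special = n_changes + n_polymorphic
    if n_special > len(window_ids):
        raise ValueError("more planted features than windows")
    special = rng.choice(len(window_ids), size=n_special, replace=False)
    changed_wids = [window_ids[i] for i in special[:n_changes]]
    poly_wids = [window_ids[i] for i in special[n_changes:]]

    # mutant-specific modifications, expressed on slot copies
    mut_slots = {wid: [dict(e) for e in entries] for wid, entries in slots.items()}
    planted_changes: list[PlantedChange] = []
    shift_counter = 0
    half = change_span // 2

    def interval_around(w: Window, center: float) -> tuple[int, int]:
        lo = max(w.start, int(round(center)) - half)
        hi = min(w.end, int(round(center)) + half - 1)
        return lo, hi

    def plant_gain(w: Window, entries, kind_tag, group=None):
        empties = [e for e in entries if not e["kept"]]
        target = empties[len(empties) // 2] if empties else None
        if target is None:
            kept = [e for e in entries if e["kept"]]
            target = kept[len(kept) // 2]
            for geno_entries in (slots[w.window_id], entries):
                for e in geno_entries:
                    if e["center"] == target["center"]:
                        e["kept"] = False
        lo, hi = interval_around(w, target["center"])
        entries.append(
            {
                "center": target["center"],
                "height": min(1.0, (2.0**delta - 1.0) * 0.75),
                "kept": True,
            }
        )
        planted_changes.append(
            PlantedChange(w.window_id, lo, hi, "gain", delta, group)
        )

    def plant_loss(w: Window, entries, group=None, avoid: float | None = None):
        kept = [
            e
            for e in entries
            if e["kept"] and (avoid is None or e["center"] != avoid)
        ]
        target = kept[len(kept) // 2]
        lo, hi = interval_around(w, target["center"])
        for e in entries:
            if e["kept"] and lo <= e["center"] <= hi:
                e["height"] *= 2.0**-delta
        planted_changes.append(
            PlantedChange(w.window_id, lo, hi, "loss", delta, group)
        )
        return target["center"]

    for j, wid in enumerate(changed_wids):
        w = layout.window(wid)
        kind = change_kinds[j % len(change_kinds)]
        entries = mut_slots[wid]
        if kind == "gain":
            plant_gain(w, entries, kind)
        elif kind == "loss":
            plant_loss(w, entries)
        else:  # shift: linked loss + adjacent gain
            shift_counter += 1
            lost_center = plant_loss(w, entries, group=shift_counter)
            plant_gain(w, entries, kind, group=shift_counter)

    polymorphisms = []
    for wid in poly_wids:
        w = layout.window(wid)
        pad = int(round(w.span * (1.0 - polymorphic_span_frac) / 2.0))
        polymorphisms.append(
            PlantedPolymorphism(wid, w.start + pad, w.end - pad, divergence)
        )

    def to_nucs(slot_map):
        return {
            wid: [
                (e["center"], NUCLEOSOME_SD, e["height"])
                for e in entries
                if e["kept"] and e["height"] > 0
            ]
            for wid, entries in slot_map.items()
        }

    return SyntheticTruth(
        nucleosomes={wild_type: to_nucs(slots), mutant: to_nucs(mut_slots)},
        planted_changes=planted_changes,
        planted_polymorphisms=polymorphisms,
        noise_sd=noise_sd,
        seed=int(seed),
        reference_genotype=reference_genotype or wild_type,
    )


def simulate_occupancy(
    layout: ProbeLayout, truth: SyntheticTruth, genotype: str
) -> dict[str, np.ndarray]:
    """Per-base occupancy in [0, 1] for each window (index 0 = window start)."""
    if genotype not in truth.nucleosomes:
        raise KeyError(f"truth has no genotype {genotype!r}")
    out = {}
    for w in layout.windows:
        x = np.arange(w.start, w.end + 1, dtype=float)
        occ = np.zeros_like(x)
        for center, sd, height in truth.nucleosomes[genotype].get(w.window_id, []):
            occ += height * np.exp(-((x - center) ** 2) / (2.0 * sd**2))
        out[w.window_id] = np.clip(occ, 0.0, 1.0)
    return out


def _polymorphism_shift(
    layout: ProbeLayout, truth: SyntheticTruth, genotype: str
) -> np.ndarray:
    """Per-probe hybridization shift from planted polymorphisms (log2 units)."""
    shift = np.zeros(layout.n_probes)
    if genotype == truth.reference_genotype:
        return shift
    for poly in truth.planted_polymorphisms:
        for r in layout.window_probe_rows(poly.window_id):
            p = layout.probes[r]
            if p.start <= poly.end and p.end >= poly.start:
                shift[r] -= poly.effect
    return shift


def simulate_signals(
    layout: ProbeLayout,
    truth: SyntheticTruth,
    genotype: str,
    n_replicates: int = 3,
) -> tuple[SignalSet, SignalSet]:
    """Draw (nucleosomal, reference) SignalSets for one genotype.

    Replicate noise streams are keyed by (seed, genotype, channel), so the
    same truth and seed always reproduce the same values, and zero noise
    yields the deterministic model signal exactly.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    occ = simulate_occupancy(layout, truth, genotype)
    mean_occ = np.empty(layout.n_probes)
    for w in layout.windows:
        arr = occ[w.window_id]
        for r in layout.window_probe_rows(w.window_id):
            p = layout.probes[r]
            mean_occ[r] = arr[p.start - w.start : p.end - w.start + 1].mean()
    shift = _polymorphism_shift(layout, truth, genotype)
    nuc_base = np.log2(mean_occ * truth.dynamic_range + truth.floor) + shift
    ref_base = truth.baseline + shift

    reps = [f"pool{i + 1}" for i in range(n_replicates)]
    out = []
    for channel, base in ((NUCLEOSOMAL, nuc_base), (REFERENCE, ref_base)):
        rng = _rng(truth.seed, genotype, channel)
        sd = truth.noise_sd.get(channel, 0.0)
        values = np.broadcast_to(
            np.asarray(base, dtype=float)[:, None], (layout.n_probes, n_replicates)
        ).copy()
        values += rng.normal(0.0, 1.0, size=values.shape) * sd
        out.append(
            SignalSet(
                genotype=genotype,
                channel=channel,
                replicate_ids=list(reps),
                probe_ids=layout.probe_ids,
                values=values,
                metadata={"units": "log2" if channel == NUCLEOSOMAL else "log2-scale"},
            )
        )
    return out[0], out[1]


def simulate_nol(
    layout: ProbeLayout,
    truth: SyntheticTruth,
    favored_genotype: str,
    distortion: float = 0.0,
    step: int = 10,
) -> NOLTrack:
    """NOL track = occupancy of the sequence-favored configuration.

    The designated genotype's occupancy is sampled every ``step`` bp across
    each window and optionally distorted with smooth (Gaussian-kernel
    filtered) noise of standard deviation ``distortion``.
    """
    occ = simulate_occupancy(layout, truth, favored_genotype)
    rng = _rng(truth.seed, "nol")
    per_chrom: dict[str, list[tuple[np.ndarray, np.ndarray]]] = {}
    kernel = np.exp(-0.5 * (np.arange(-10, 11) / 4.0) ** 2)
    kernel /= kernel.sum()
    for w in layout.windows:
        pos = np.arange(w.start, w.end + 1, step, dtype=float)
        if pos[-1] != w.end:
            pos = np.append(pos, float(w.end))
        score = occ[w.window_id][(pos - w.start).astype(int)].copy()
        if distortion > 0:
            raw = rng.normal(0.0, 1.0, size=score.size + 20)
            smooth = np.convolve(raw, kernel, mode="valid")
            smooth *= distortion / max(smooth.std(), 1e-12)
            score += smooth[: score.size]
        per_chrom.setdefault(w.chrom, []).append((pos, score))
    data = {}
    for chrom, parts in per_chrom.items():
        pos = np.concatenate([p for p, _ in parts])
        score = np.concatenate([s for _, s in parts])
        order = np.argsort(pos, kind="stable")
        data[chrom] = (pos[order], score[order])
    return NOLTrack(data)


# ---------------------------------------------------------------------------
# qPCR simulation
# ---------------------------------------------------------------------------


def simulate_ct(
    design: pd.DataFrame,
    noise_sd: float = 0.0,
    seed: int = 0,
    n_technical: int = 2,
    intercept: float = 25.0,
) -> pd.DataFrame:
    """Ct table from true relative quantities: Ct = intercept - log2(q) + noise.

    ``design`` needs columns target, sample, genotype, assay, quantity
    (quantity > 0).  Each design row yields ``n_technical`` wells with
    independent noise (efficiency fixed at 2: one cycle per 2-fold).
    """
    required = {"target", "sample", "genotype", "assay", "quantity"}
    missing = required - set(design.columns)
    if missing:
        raise ValueError(f"design missing columns: {sorted(missing)}")
    if (design["quantity"] <= 0).any():
        raise ValueError("quantities must be positive")
    rng = _rng(seed, "ct")
    rows = []
    for rec in design.to_dict("records"):
        base = intercept - np.log2(rec["quantity"])
        for t in range(n_technical):
            rows.append(
                {
                    "target": rec["target"],
                    "sample": rec["sample"],
                    "genotype": rec["genotype"],
                    "assay": rec["assay"],
                    "tech_rep": t + 1,
                    "ct": float(base + rng.normal(0.0, 1.0) * noise_sd),
                }
            )
    return pd.DataFrame(rows)


def np_assay_design(
    target: str = "Fdx3_NP1",
    control_locus: str = "Mwp1",
    genotypes: tuple[str, str] = ("WT", "mut"),
    n_samples: int = 3,
    protection: float = 0.5,
    mutant_fold: float = 0.5,
) -> pd.DataFrame:
    """MNase-qPCR design: mutant protection at ``target`` scaled by ``mutant_fold``."""
    wt, mut = genotypes
    rows = []
    for g in genotypes:
        for i in range(n_samples):
            sample = f"{g}_s{i + 1}"
            for locus in (target, control_locus):
                q = protection
                if locus == target and g == mut:
                    q = protection * mutant_fold
                rows.append((locus, sample, g, "mnase", q))
                rows.append((locus, sample, g, "gdna", 1.0))
    return pd.DataFrame(
        rows, columns=["target", "sample", "genotype", "assay", "quantity"]
    )


def expression_design(
    target: str = "Chr156",
    reference_gene: str = "UbiConj",
    genotypes: tuple[str, str] = ("WT", "mut"),
    n_samples: int = 3,
    mutant_fold: float = 0.5,
) -> pd.DataFrame:
    """qRT-PCR design: mutant expresses ``target`` at ``mutant_fold`` x wild type."""
    wt, mut = genotypes
    rows = []
    for g in genotypes:
        for i in range(n_samples):
            sample = f"{g}_s{i + 1}"
            q = mutant_fold if g == mut else 1.0
            rows.append((target, sample, g, "cdna", q))
            rows.append((reference_gene, sample, g, "cdna", 1.0))
    return pd.DataFrame(
        rows, columns=["target", "sample", "genotype", "assay", "quantity"]
    )
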