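"""Seeded synthetic-data generators.

Everything here exists so the whole pipeline is testable without any
download: random circular genomes at a controlled GC content, motif
planting (with rejection-sampled motif-free backgrounds), mutation
catalogs with a known class mix, and amplicon count tables with programmed
efficiency, product purity, strand split and uniform sequencing error.
All generators are deterministic under their seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .catalog import MutationRecord
from .genome import CircularGenome, complement, reverse_complement
from .quant import BASES, CONVERSIONS, CountTable
from .registry import IUPAC_SETS, iupac_match


def random_circular_genome(length: int, gc: float = 0.5, seed: int = 0,
                           name: str | None = None) -> CircularGenome:
    """i.i.d. bases: G and C each at gc/2, A and T each at (1-gc)/2."""
    if length < 10:
        raise ValueError("length must be >= 10")
    if not 0.0 <= gc <= 1.0:
        raise ValueError("gc must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    seq = "".join(rng.choice(["A", "C", "G", "T"], size=length, p=probs))
    return CircularGenome(name=name or f"synthetic_seed{seed}", sequence=seq)


def _concrete_instance(pattern: str, rng: np.random.Generator) -> str:
    return "".join(b if b in "ACGT" else rng.choice(sorted(IUPAC_SETS[b]))
                   for b in pattern)


def plant_motif(genome: CircularGenome, pattern: str, position: int,
                strand: str = "top", seed: int = 0,
                instance: str | None = None) -> CircularGenome:
    """Write a concrete instance of ``pattern`` at ``position`` (0-based,
    wrapping allowed) on the given strand; degenerate letters are sampled
    by seed unless a concrete ``instance`` is supplied."""
    rng = np.random.default_rng(seed)
    inst = instance or _concrete_instance(pattern, rng)
    if not iupac_match(pattern, inst):
        raise ValueError(f"{inst!r} is not an instance of {pattern!r}")
    top_text = inst if strand == "top" else reverse_complement(inst)
    n = genome.length
    seq = list(genome.sequence)
    for i, b in enumerate(top_text):
        seq[(position + i) % n] = b
    return CircularGenome(name=genome.name, sequence="".join(seq),
                          topology=genome.topology)


def motif_free_genome(length: int, forbidden: list[str], gc: float = 0.5,
                      seed: int = 0, max_tries: int = 10_000) -> CircularGenome:
    """Random genome containing no occurrence of any forbidden IUPAC pattern
    on either strand (circular), by per-window rejection resampling."""
    rng = np.random.default_rng(seed)
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    seq = list(rng.choice(["A", "C", "G", "T"], size=length, p=probs))

    def offending(s: list[str]) -> int | None:
        doubled = "".join(s) + "".join(s)
        for pat in forbidden:
            k = len(pat)
            for i in range(length):
                w = doubled[i : i + k]
                if iupac_match(pat, w) or iupac_match(pat, reverse_complement(w)):
                    return i
        return None

    for _ in range(max_tries):
        i = offending(seq)
        if i is None:
            return CircularGenome(name=f"motif_free_seed{seed}", sequence="".join(seq))
        kmax = max(len(p) for p in forbidden)
        for j in range(i, i + kmax):
            seq[j % length] = rng.choice(["A", "C", "G", "T"], p=probs)
    raise RuntimeError("could not scrub all forbidden motifs")


def random_catalog(n: int, class_mix: dict[str, float], seed: int = 0,
                   genome: CircularGenome | None = None) -> list[MutationRecord]:
    """Catalog of n records drawn from a class mix over
    {A>G, G>A, C>T, T>C, transversion}. With a genome, positions are chosen
    so the reference base matches; otherwise positions are arbitrary."""
    rng = np.random.default_rng(seed)
    classes = sorted(class_mix)
    probs = np.array([class_mix[c] for c in classes], dtype=float)
    probs = probs / probs.sum()
    transversions = [("A", "C"), ("A", "T"), ("C", "A"), ("C", "G"),
                     ("G", "C"), ("G", "T"), ("T", "A"), ("T", "G")]
    records = []
    for i in range(n):
        cls = rng.choice(classes, p=probs)
        if cls == "transversion":
            ref, alt = transversions[rng.integers(len(transversions))]
        else:
            ref, alt = cls.split(">")
        if genome is not None:
            pool = [j for j, b in enumerate(genome.sequence) if b == ref]
            if not pool:
                raise ValueError(f"genome has no {ref} for class {cls}")
            pos = int(pool[rng.integers(len(pool))]) + 1
        else:
            pos = int(rng.integers(1, 16570))
        records.append(MutationRecord(pos, ref, alt, label=str(cls)))
    return records


@dataclass
class SimulatedCounts:
    treated: CountTable
    control: CountTable
    editable_positions: dict[int, str]  # 1-based -> attributed strand


def simulate_count_table(window_seq: str, start: int, editor: str = "ABE",
                         efficiency: float = 0.3, purity: float = 1.0,
                         strand_split: float = 1.0, depth: int = 10_000,
                         error_rate: float = 0.0005, seed: int = 0,
                         ) -> SimulatedCounts:
    """Treated + control count tables for a top-strand amplicon window.

    Every substrate position is edited binomially: top-attributed positions
    (ref A for ABE, ref C for CBE) at ``efficiency * strand_split``,
    bottom-attributed (ref T / ref G) at ``efficiency * (1 - strand_split)``.
    Edited reads carry the intended product with probability ``purity``
    (the remainder split between the two other bases); unedited reads error
    uniformly to the three other bases at ``error_rate``. The control has
    error only.
    """
    for r, nm in [(efficiency, "efficiency"), (purity, "purity"),
                  (strand_split, "strand_split"), (error_rate, "error_rate")]:
        if not 0.0 <= r <= 1.0:
            raise ValueError(f"{nm} must lie in [0, 1]")
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if editor not in CONVERSIONS:
        raise ValueError("editor must be 'ABE' or 'CBE'")
    rng = np.random.default_rng(seed)
    conv = CONVERSIONS[editor]
    editable: dict[int, str] = {}
    rows_t, rows_c = [], []
    for i, ref in enumerate(window_seq.upper()):
        pos = start + i
        rate = 0.0
        product = None
        if ref in conv:
            product, strand = conv[ref]
            rate = efficiency * (strand_split if strand == "top" else 1 - strand_split)
            editable[pos] = strand
        rows_t.append(_draw_row(pos, ref, depth, rate, product, purity, error_rate, rng))
        rows_c.append(_draw_row(pos, ref, depth, 0.0, product, purity, error_rate, rng))
    treated = CountTable(pd.DataFrame(rows_t), sample="treated")
    control = CountTable(pd.DataFrame(rows_c), sample="control")
    return SimulatedCounts(treated, control, editable)


def _draw_row(pos: int, ref: str, depth: int, rate: float, product: str | None,
              purity: float, error_rate: float, rng: np.random.Generator) -> dict:
    counts = {b: 0 for b in BASES}
    edited = int(rng.binomial(depth, rate)) if product else 0
    unedited = depth - edited
    if edited:
        intended = int(rng.binomial(edited, purity))
        counts[product] += intended
        others = [b for b in BASES if b not in (ref, product)]
        spill = edited - intended
        split = rng.multinomial(spill, [0.5, 0.5]) if spill else (0, 0)
        for b, c in zip(others, split):
            counts[b] += int(c)
    errs = int(rng.binomial(unedited, error_rate))
    counts[ref] += unedited - errs
    err_targets = [b for b in BASES if b != ref]
    for b, c in zip(err_targets, rng.multinomial(errs, [1 / 3] * 3) if errs else (0, 0, 0)):
        counts[b] += int(c)
    return {"position": pos, "ref": ref, **counts}
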