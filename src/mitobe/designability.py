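"""Genome-wide designable targeting range and motif-density tracks.

A position is designable for a motif-anchored nickase when it lies within
``flank`` bp (default 20, upstream or downstream) of some nick position —
the deaminase arm can be placed to expose it. Sequence-unrestricted
nickases (Nt.BspD6I(C)) cover every position by definition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome import CircularGenome
from .registry import NickaseSpec, scan_motifs


@dataclass
class DesignabilityTrack:
    genome_name: str
    nickase: str
    flank: int
    mask: np.ndarray  # bool, per genome position
    coverage_fraction: float
    density: np.ndarray | None = None  # per-window site counts
    density_window: int | None = None
    density_step: int | None = None

    def designable(self, position_1based: int) -> bool:
        return bool(self.mask[(position_1based - 1) % len(self.mask)])


def designable_mask(genome: CircularGenome, nickase: NickaseSpec,
                    flank: int = 20, dedup_palindromes: bool = True,
                    ) -> DesignabilityTrack:
    """Union of closed +/-flank windows around every nick position."""
    if flank < 0:
        raise ValueError("flank must be >= 0")
    n = genome.length
    mask = np.zeros(n, dtype=bool)
    if nickase.motif == "":
        mask[:] = True
        return DesignabilityTrack(genome.name, nickase.name, flank, mask, 1.0)
    sites = scan_motifs(genome, nickase, dedup_palindromes=dedup_palindromes)
    for s in sites:
        q = s.nick_position
        if 2 * flank + 1 >= n:
            mask[:] = True
            break
        idx = (np.arange(q - flank, q + flank + 1)) % n
        mask[idx] = True
    cov = float(mask.sum()) / n
    return DesignabilityTrack(genome.name, nickase.name, flank, mask, cov)


def density_track(genome: CircularGenome, nickase: NickaseSpec,
                  window: int = 40, step: int | None = None,
                  dedup_palindromes: bool = True) -> np.ndarray:
    """Per-window counts of recognition sites whose duplex_start falls in
    each (circularly tiled) window. Non-overlapping tiling by default."""
    if window < len(nickase.motif):
        raise ValueError("window must be at least the motif length")
    step = window if step is None else step
    n = genome.length
    sites = scan_motifs(genome, nickase, dedup_palindromes=dedup_palindromes)
    starts = np.arange(0, n, step)
    counts = np.zeros(len(starts), dtype=int)
    for s in sites:
        for wi, wstart in enumerate(starts):
            if (s.duplex_start - wstart) % n < window:
                counts[wi] += 1
    return counts


def track_to_bedgraph(track: DesignabilityTrack, counts: np.ndarray,
                      window: int, step: int, genome_name: str | None = None) -> str:
    name = genome_name or track.genome_name
    lines = []
    n = len(track.mask)
    for wi, c in enumerate(counts):
        start = wi * step
        end = min(start + window, n)
        lines.append(f"{name}\t{start}\t{end}\t{c}")
    return "\n".join(lines) + "\n"


def mask_to_bed(track: DesignabilityTrack, genome_name: str | None = None) -> str:
    """Designable intervals as BED (wraparound runs split at the origin)."""
    name = genome_name or track.genome_name
    m = track.mask
    n = len(m)
    lines = []
    i = 0
    while i < n:
        if m[i]:
            j = i
            while j < n and m[j]:
                j += 1
            lines.append(f"{name}\t{i}\t{j}\t{track.nickase}_designable")
            i = j
        else:
            i += 1
    return "\n".join(lines) + ("\n" if lines else "")


def plot_tracks(genome: CircularGenome, tracks: list[DesignabilityTrack], path):
    """Plain linear rendering of designability masks (one row per nickase)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(10, 1 + len(tracks)))
    for i, t in enumerate(tracks):
        x = np.arange(genome.length)
        ax.fill_between(x, i, i + 0.8 * t.mask, step="mid", label=f"{t.nickase} "
                        f"({100 * t.coverage_fraction:.1f}%)")
    ax.set_yticks([])
    ax.set_xlabel(f"{genome.name} position (bp)")
    ax.legend(loc="upper right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
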