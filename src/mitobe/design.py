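"""Enumerate, validate and rank dimeric mitoBE designs.

A dimeric design places two TALE arms on opposite strands around a spacer
(the editing window): the left arm binds the top strand 5' of the window,
the right arm binds the bottom strand 3' of it. One arm carries the nickase,
the other the deaminase. The nickase's gap-to-motif rule decides which
strand is nicked; deamination products are retained on the strand that is
NOT nicked, so the edited strand is always the non-nicked one.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .genome import CircularGenome, GenomicInterval, complement, reverse_complement
from .registry import (
    DeaminaseSpec,
    EDITOR_CLASSES,
    MotifSite,
    NickaseSpec,
    OPPOSITE_OF_TALE,
    SAME_AS_TALE,
    UNSUPPORTED,
    scan_motifs,
)

RVD_CODE = {"A": "NI", "C": "HD", "G": "NN", "T": "NG"}

#: which duplex strand a TALE arm recognizes, by side
ARM_STRAND = {"left": "top", "right": "bottom"}
_OTHER = {"top": "bottom", "bottom": "top"}


def rvds_for(sequence: str) -> str:
    """RVD string for a bound sequence (NI->A, HD->C, NN->G, NG->T)."""
    try:
        return " ".join(RVD_CODE[b] for b in sequence)
    except KeyError as e:
        raise ValueError(f"cannot derive RVDs for base {e}") from None


@dataclass(frozen=True)
class TaleArm:
    """One TALE arm: left arms bind the top strand, right arms the bottom."""

    side: str
    binding: GenomicInterval
    bound_seq: str  # 5'->3' on the arm's strand
    preceded_by_t: bool

    def __post_init__(self) -> None:
        if self.side not in ARM_STRAND:
            raise ValueError("side must be 'left' or 'right'")
        if self.binding.strand != ARM_STRAND[self.side]:
            raise ValueError(f"{self.side} arm must bind the {ARM_STRAND[self.side]} strand")

    @property
    def rvd_sequence(self) -> str:
        return rvds_for(self.bound_seq)


@dataclass(frozen=True)
class EditRequest:
    """A requested duplex base change at a 1-based top-strand position."""

    position: int
    ref: str
    desired: str

    def __post_init__(self) -> None:
        pair = (self.ref, self.desired)
        if pair not in _REQUEST_TABLE:
            raise ValueError(
                f"{self.ref}->{self.desired} is not a deamination-reachable change; "
                "supported: A>G, T>C (mitoABE), C>T, G>A (mitoCBE)")

    @property
    def editor_class(self) -> str:
        return _REQUEST_TABLE[(self.ref, self.desired)][0]

    @property
    def required_edited_strand(self) -> str:
        """Strand that must be single-stranded-edited: the strand carrying
        the deaminase substrate base at the target."""
        return _REQUEST_TABLE[(self.ref, self.desired)][1]

    @property
    def deaminase(self) -> DeaminaseSpec:
        return EDITOR_CLASSES[self.editor_class]


# (ref on top, desired on top) -> (editor class, strand carrying substrate)
_REQUEST_TABLE = {
    ("A", "G"): ("mitoABE", "top"),
    ("T", "C"): ("mitoABE", "bottom"),  # edited A sits on the bottom strand
    ("C", "T"): ("mitoCBE", "top"),
    ("G", "A"): ("mitoCBE", "bottom"),
}


@dataclass
class DesignParams:
    """Tunable geometry and scoring knobs with editor-derived defaults."""

    window_min: int = 8
    window_max: int = 24
    arm_min: int = 14
    arm_max: int = 18
    require_preceding_t: bool = True
    muth_star_motif: str = "GATN"
    w_bystander: float = 1.0
    w_gap3: float = 0.5
    w_class_prior: float = 0.25
    w_centrality: float = 0.25


@dataclass(frozen=True)
class DesignCandidate:
    """A fully specified dimeric design for one edit request."""

    nickase_arm: TaleArm
    deaminase_arm: TaleArm
    nickase: NickaseSpec
    deaminase: DeaminaseSpec
    anchor_site: MotifSite | None
    gap: int | None
    window: GenomicInterval  # spacer between the arms, top-strand coords
    nick_strand: str
    edited_strand: str
    target_position: int  # 1-based
    target_offset: int  # 0-based offset of the target within the window
    target_in_window: bool
    bystanders: tuple[int, ...]  # 1-based positions, sorted
    score: float = 0.0

    @property
    def nickase_side(self) -> str:
        return self.nickase_arm.side

    def tie_key(self) -> tuple:
        return (-self.score, len(self.window), self.window.start,
                0 if self.nickase_arm.side == "left" else 1)


def predict_nick_strand(gap: int, nickase: NickaseSpec, nickase_arm_side: str) -> str:
    """Resolve the gap->strand rule against the nickase arm's recognition
    strand (left arm -> top, right arm -> bottom); returns "top", "bottom"
    or "unsupported"."""
    if not nickase.validated:
        raise ValueError(
            f"{nickase.name} was screened but its strand rule is uncharacterized; "
            "no nick-strand prediction is available")
    if gap < 0:
        raise ValueError("gap must be >= 0")
    outcome = nickase.rule_for_gap(gap)
    if outcome == UNSUPPORTED:
        return UNSUPPORTED
    tale_strand = ARM_STRAND[nickase_arm_side]
    return tale_strand if outcome == SAME_AS_TALE else _OTHER[tale_strand]


def bystanders_in_window(genome: CircularGenome, window: GenomicInterval,
                         edited_strand: str, substrate: str,
                         target_position: int) -> tuple[int, ...]:
    """1-based positions in the window whose edited-strand base is the
    deaminase substrate, excluding the target. Motif-internal bases count:
    every substrate base exposed on the nicked-open strand is editable."""
    n = genome.length
    out = []
    # substrate on the bottom strand shows as its complement on top
    top_equiv = substrate if edited_strand == "top" else complement(substrate)
    for off in range(len(window)):
        pos0 = (window.start + off) % n
        if genome.sequence[pos0] == top_equiv and pos0 + 1 != target_position:
            out.append(pos0 + 1)
    return tuple(sorted(out))


def score_design(candidate: DesignCandidate, params: DesignParams | None = None) -> float:
    """Deterministic heuristic score.

    Penalises bystanders, rewards the empirically best 3-bp gap for
    MutH/MutH*, prefers the strand-precise nickases over Nt.BspD6I(C), and
    rewards a target centred in the window.
    """
    p = params or DesignParams()
    score = -p.w_bystander * len(candidate.bystanders)
    if candidate.gap == 3 and candidate.nickase.name in ("MutH", "MutH*"):
        score += p.w_gap3
    if candidate.nickase.name in ("MutH", "MutH*"):
        score += p.w_class_prior
    wlen = len(candidate.window)
    # distance of the target from the window centre, 0 (centre) .. 1 (edge)
    off = candidate.target_offset
    centre_dist = abs(off - (wlen - 1) / 2) / max((wlen - 1) / 2, 1e-9)
    score += p.w_centrality * (1.0 - centre_dist)
    return score


def enumerate_designs(genome: CircularGenome, request: EditRequest,
                      nickase: NickaseSpec, params: DesignParams | None = None,
                      ) -> tuple[list[DesignCandidate], dict[str, int]]:
    """All dimeric designs satisfying the geometry and strand constraints.

    Returns the candidate list (score-sorted, deterministic tie-breaks) and
    a machine-readable summary of why placements were rejected, so an empty
    result is diagnosable (no motif in range / wrong strand / window bounds
    / arm constraints).
    """
    p = params or DesignParams()
    n = genome.length
    t0 = (request.position - 1) % n
    actual = genome.sequence[t0]
    if actual != request.ref:
        raise ValueError(
            f"reference mismatch at position {request.position}: genome has "
            f"{actual}, request says {request.ref}")
    deaminase = request.deaminase
    need_strand = request.required_edited_strand
    reasons = {"no_motif_in_range": 0, "wrong_strand": 0, "gap_unsupported": 0,
               "arm_constraints": 0}
    if not nickase.validated:
        raise ValueError(f"{nickase.name} is unvalidated; no design rules available")

    motif_sites = scan_motifs(genome, nickase) if nickase.motif else None
    k = len(nickase.motif)

    candidates: list[DesignCandidate] = []
    for wlen in range(p.window_min, p.window_max + 1):
        if wlen > n:
            break
        for off in range(wlen):  # target offset within the window
            ws = (t0 - off) % n
            window = GenomicInterval(ws, ws + wlen)
            # anchor options: (site, gap when nickase on left, on right)
            if motif_sites is not None:
                anchors = []
                for site in motif_sites:
                    r = (site.duplex_start - ws) % n
                    if r + k <= wlen:
                        anchors.append((site, r, wlen - (r + k)))
                if not anchors:
                    reasons["no_motif_in_range"] += 1
                    continue
            else:
                anchors = [(None, None, None)]

            for site, gap_left, gap_right in anchors:
                for nick_side in ("left", "right"):
                    gap = gap_left if nick_side == "left" else gap_right
                    if site is not None:
                        nick_strand = predict_nick_strand(gap, nickase, nick_side)
                        if nick_strand == UNSUPPORTED:
                            reasons["gap_unsupported"] += 1
                            continue
                        # non-palindromic motifs are cut only on the strand
                        # that carries them
                        if not nickase.palindromic and nick_strand != site.strand:
                            reasons["wrong_strand"] += 1
                            continue
                    else:
                        nick_strand = ARM_STRAND[nick_side]
                    edited_strand = _OTHER[nick_strand]
                    if edited_strand != need_strand:
                        reasons["wrong_strand"] += 1
                        continue
                    arm_pairs = _arm_placements(genome, ws, wlen, p)
                    if not arm_pairs:
                        reasons["arm_constraints"] += 1
                        continue
                    bys = bystanders_in_window(genome, window, edited_strand,
                                               deaminase.substrate, request.position)
                    for left_arm, right_arm in arm_pairs:
                        nick_arm, deam_arm = ((left_arm, right_arm)
                                              if nick_side == "left"
                                              else (right_arm, left_arm))
                        cand = DesignCandidate(
                            nickase_arm=nick_arm, deaminase_arm=deam_arm,
                            nickase=nickase, deaminase=deaminase,
                            anchor_site=site, gap=gap, window=window,
                            nick_strand=nick_strand, edited_strand=edited_strand,
                            target_position=request.position, target_offset=off,
                            target_in_window=True, bystanders=bys)
                        cand = replace(cand, score=score_design(cand, p))
                        candidates.append(cand)
    candidates.sort(key=DesignCandidate.tie_key)
    return candidates, reasons


def _arm_placements(genome: CircularGenome, ws: int, wlen: int,
                    p: DesignParams) -> list[tuple[TaleArm, TaleArm]]:
    """All (left arm, right arm) pairs flanking window [ws, ws+wlen)."""
    n = genome.length
    we = ws + wlen
    lefts = []
    for alen in range(p.arm_min, p.arm_max + 1):
        start = (ws - alen) % n
        iv = GenomicInterval(start, start + alen, strand="top")
        seq = genome.fetch(iv)
        t_ok = genome.base(ws - alen - 1) == "T"
        if p.require_preceding_t and not t_ok:
            continue
        lefts.append(TaleArm(side="left", binding=iv, bound_seq=seq, preceded_by_t=t_ok))
    rights = []
    for alen in range(p.arm_min, p.arm_max + 1):
        start = we % n
        iv = GenomicInterval(start, start + alen, strand="bottom")
        seq = genome.fetch(iv)  # 5'->3' on bottom strand
        # base 5' of the bottom-strand site is the complement of the top base
        # just past the binding interval
        t_ok = complement(genome.base(we + alen)) == "T"
        if p.require_preceding_t and not t_ok:
            continue
        rights.append(TaleArm(side="right", binding=iv, bound_seq=seq, preceded_by_t=t_ok))
    return [(l, r) for l in lefts for r in rights]


def tale_offtarget_scan(genome: CircularGenome, arm: TaleArm,
                        max_mismatch: int = 1, flank: int = 50,
                        ) -> list[tuple[int, str, int, GenomicInterval]]:
    """Genome locations (both strands, circular) matching the arm's binding
    sequence with <= max_mismatch substitutions, excluding the on-target
    site. Each hit: (start, strand, mismatches, +/-flank interval)."""
    if max_mismatch not in (0, 1, 2):
        raise ValueError("max_mismatch must be 0, 1 or 2")
    n = genome.length
    probe = arm.bound_seq
    k = len(probe)
    doubled = genome.sequence + genome.sequence
    on_target = (arm.binding.start % n, arm.binding.strand)
    hits = []
    for strand in ("top", "bottom"):
        for start in range(n):
            window = doubled[start : start + k]
            text = window if strand == "top" else reverse_complement(window)
            mm = sum(1 for a, b in zip(probe, text) if a != b)
            if mm <= max_mismatch and (start, strand) != on_target:
                fl_start = (start - flank) % n
                iv = GenomicInterval(fl_start, fl_start + min(k + 2 * flank, n), strand="top")
                hits.append((start, strand, mm, iv))
    return hits


def designs_to_table(candidates: list[DesignCandidate]):
    """Candidates as a pandas DataFrame (one row per design)."""
    import pandas as pd

    rows = []
    for c in candidates:
        rows.append({
            "nickase": c.nickase.name,
            "deaminase": c.deaminase.name,
            "nickase_side": c.nickase_arm.side,
            "left_arm_start_1based": (c.nickase_arm.binding.start
                                      if c.nickase_arm.side == "left"
                                      else c.deaminase_arm.binding.start) + 1,
            "window_start_1based": c.window.start + 1,
            "window_length": len(c.window),
            "gap": c.gap if c.gap is not None else "",
            "anchor_motif": c.anchor_site.matched_seq if c.anchor_site else "",
            "nick_strand": c.nick_strand,
            "edited_strand": c.edited_strand,
            "target_position": c.target_position,
            "n_bystanders": len(c.bystanders),
            "bystanders": ",".join(map(str, c.bystanders)),
            "nickase_arm_rvds": c.nickase_arm.rvd_sequence,
            "deaminase_arm_rvds": c.deaminase_arm.rvd_sequence,
            "score": c.score,
        })
    return pd.DataFrame(rows)
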