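"""Nickase and deaminase specifications plus recognition-site scanning.

The strand-selective editors modelled here pair a TALE-fused nickase with a
TALE-fused single-strand deaminase. Which strand the nickase cuts depends on
the gap between the nickase-TALE binding site and the recognition motif:
for MutH (5'-|GATC-3') and its relaxed variant MutH* a gap of 0-4 bp nicks
the strand opposite the TALE's recognition strand, 5-9 bp nicks the TALE
recognition strand itself, and larger gaps are uncharacterized. Nt.BspD6I(C)
has no recognition sequence and nicks the strand its TALE recognizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .genome import CircularGenome, reverse_complement

IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}

OPPOSITE_OF_TALE = "opposite_of_tale"
SAME_AS_TALE = "same_as_tale"
UNSUPPORTED = "unsupported"


def iupac_match(pattern: str, window: str) -> bool:
    """True iff every window base lies in the degeneracy set of the
    corresponding pattern letter. An N in the *window* (an undetermined
    genome base) matches nothing, including pattern N — conservative site
    calling."""
    if len(pattern) != len(window):
        raise ValueError("pattern and window lengths differ")
    for p, b in zip(pattern, window):
        try:
            allowed = IUPAC_SETS[p]
        except KeyError:
            raise ValueError(f"unknown IUPAC letter {p!r}") from None
        if b not in allowed:  # window N is not in any set
            return False
    return True


@dataclass(frozen=True)
class NickaseSpec:
    """A nickase: recognition motif (on the nicked strand, 5'->3'), nick
    offset from the motif's 5' end, and the gap->strand rule table."""

    name: str
    motif: str  # IUPAC pattern; empty = sequence-unrestricted
    nick_offset: int = 0
    palindromic: bool = False
    # gap (bp) -> OPPOSITE_OF_TALE / SAME_AS_TALE; gaps absent -> unsupported
    distance_rule: dict[int, str] = field(default_factory=dict)
    validated: bool = False

    def rule_for_gap(self, gap: int) -> str:
        if self.motif == "":
            # sequence-unrestricted nickases cut the TALE recognition strand
            # at any geometry
            return self.distance_rule.get(-1, SAME_AS_TALE)
        return self.distance_rule.get(gap, UNSUPPORTED)


@dataclass(frozen=True)
class DeaminaseSpec:
    """A single-strand DNA deaminase: the base it edits and the product."""

    name: str
    substrate: str  # base edited on ssDNA
    product: str
    editor_class: str  # "mitoABE" or "mitoCBE"


_MUTH_RULE = {g: OPPOSITE_OF_TALE for g in range(0, 5)} | {g: SAME_AS_TALE for g in range(5, 10)}

MUTH = NickaseSpec(name="MutH", motif="GATC", nick_offset=0, palindromic=True,
                   distance_rule=dict(_MUTH_RULE), validated=True)
# Relaxed-specificity MutH (E91A/F94A). Default motif GATN; GATD available
# via muth_star(motif="GATD") for the strict reading that GATC is rejected.
MUTH_STAR = NickaseSpec(name="MutH*", motif="GATN", nick_offset=0, palindromic=False,
                        distance_rule=dict(_MUTH_RULE), validated=True)
NT_BSPD6I_C = NickaseSpec(name="Nt.BspD6I(C)", motif="", nick_offset=0, palindromic=False,
                          distance_rule={-1: SAME_AS_TALE}, validated=True)
# Screened but uncharacterized: registry entries only, no strand rule.
I_TEVI = NickaseSpec(name="I-TevI", motif="CNNNG", nick_offset=0, validated=False)
NT_CVIPII = NickaseSpec(name="Nt.CviPII", motif="CCD", nick_offset=0, validated=False)

TADA8E_V106W = DeaminaseSpec(name="TadA8e-V106W", substrate="A", product="G",
                             editor_class="mitoABE")
RAPOBEC1 = DeaminaseSpec(name="rAPOBEC1-2xUGI", substrate="C", product="T",
                         editor_class="mitoCBE")

NICKASES: dict[str, NickaseSpec] = {n.name: n for n in
                                    (MUTH, MUTH_STAR, NT_BSPD6I_C, I_TEVI, NT_CVIPII)}
DEAMINASES: dict[str, DeaminaseSpec] = {d.name: d for d in (TADA8E_V106W, RAPOBEC1)}
EDITOR_CLASSES: dict[str, DeaminaseSpec] = {"mitoABE": TADA8E_V106W, "mitoCBE": RAPOBEC1}


def muth_star(motif: str = "GATN") -> NickaseSpec:
    """MutH* with a configurable motif (GATN default, GATD optional)."""
    if motif not in ("GATN", "GATD"):
        raise ValueError("MutH* motif must be GATN or GATD")
    return NickaseSpec(name="MutH*", motif=motif, nick_offset=0, palindromic=False,
                       distance_rule=dict(_MUTH_RULE), validated=True)


def get_nickase(name: str, muth_star_motif: str = "GATN") -> NickaseSpec:
    if name == "MutH*":
        return muth_star(muth_star_motif)
    try:
        return NICKASES[name]
    except KeyError:
        raise ValueError(f"unknown nickase {name!r}; known: {sorted(NICKASES)}") from None


@dataclass(frozen=True)
class MotifSite:
    """One recognition-site occurrence on the duplex.

    duplex_start is the 0-based top-strand coordinate of the motif window's
    leftmost base; strand is the motif-carrying strand; nick_position is the
    0-based top-strand coordinate of the base immediately 3' of the nick on
    the motif-carrying strand.
    """

    duplex_start: int
    strand: str
    matched_seq: str
    nick_position: int
    nickase: str

    def sort_key(self) -> tuple[int, int]:
        return (self.duplex_start, 0 if self.strand == "top" else 1)


def scan_motifs(genome: CircularGenome, nickase: NickaseSpec,
                dedup_palindromes: bool = True) -> list[MotifSite]:
    """All recognition-site occurrences on both strands of the circular
    genome, including windows spanning the origin.

    When both strands match the pattern at the same duplex window (always
    true for a GATC window, whether scanning GATC or GATN) the two matches
    describe one duplex recognition site; with ``dedup_palindromes`` they
    are reported once, as the top-strand occurrence.
    """
    if nickase.motif == "":
        raise ValueError(
            f"{nickase.name} has no recognition sequence; design without motif anchoring"
        )
    pattern = nickase.motif
    k = len(pattern)
    n = genome.length
    if k > n:
        return []
    doubled = genome.sequence + genome.sequence
    sites: list[MotifSite] = []
    for p in range(n):
        window = doubled[p : p + k]
        top_hit = iupac_match(pattern, window)
        # motif on the bottom strand occupying the same duplex window reads
        # 5'->3' as the reverse complement of the top window
        bottom_read = reverse_complement(window)
        bottom_hit = "N" not in window and iupac_match(pattern, bottom_read)
        if top_hit:
            sites.append(MotifSite(
                duplex_start=p, strand="top", matched_seq=window,
                nick_position=(p + nickase.nick_offset) % n, nickase=nickase.name))
        if bottom_hit and not (top_hit and dedup_palindromes):
            sites.append(MotifSite(
                duplex_start=p, strand="bottom", matched_seq=bottom_read,
                nick_position=(p + k - 1 - nickase.nick_offset) % n,
                nickase=nickase.name))
    sites.sort(key=MotifSite.sort_key)
    return sites


def sites_to_bed(sites: list[MotifSite], genome: CircularGenome) -> str:
    """BED6 text for a site list (wraparound windows split into two lines)."""
    from .genome import GenomicInterval

    lines = []
    for s in sites:
        k = len(s.matched_seq)
        iv = GenomicInterval(s.duplex_start, s.duplex_start + k,
                             strand=s.strand if s.strand in ("top", "bottom") else "top")
        for frag in iv.to_bed_lines(genome.length, name=s.nickase):
            lines.append(genome.name + frag)
    return "\n".join(lines) + ("\n" if lines else "")
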