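"""Oligo layout, in-vitro recombineering and genomic-integration simulation.

The three sequence artifacts are modelled exactly:

* an **oligo** — ``overlap_A | spacer | terminator | ha_down | BstXI | ha_up |
  overlap_B`` — whose terminal overlaps are identical to the two ends of the
  feature cassette;
* the **circular intermediate** formed by homology-overlap assembly of one
  oligo with one cassette;
* the **SIC** released from the rolling-circle concatemer by BstXI digestion
  between the homology arms (cut modelled at the centre of the interrupted
  site, leaving ≤6-nt terminal residuals).

Integration is simulated as homologous recombination: both arms are located
in the target chromosome (approximate matching, modelling strand invasion
with tolerated heterology), the intervening span is replaced by the SIC
core, and the resulting fusion is checked for reading frame.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import edlib
import numpy as np

from ._seq import STOP_CODONS, first_stop_codon, revcomp
from .genome import AnnotatedGenome, OrfRecord
from .targets import (
    DEFAULT_TERMINATOR,
    CandidateTarget,
    DesignRules,
    insertion_point,
)

BSTXI_REGEX = re.compile(r"(?=(CCA[ACGT]{6}TGG))")

#: fixed hexamer of the interrupted BstXI recognition site on the oligo
DEFAULT_BSTXI_SITE = "CCA" + "GTCTGA" + "TGG"

#: FnCas12a-style direct repeat; its 3' end cannot complete a TTV/TYN PAM.
DIRECT_REPEAT = "AATTTCTACTGTTGTAGAT"


class AssemblyError(ValueError):
    """Raised when a recombineering step cannot proceed."""


def count_bstxi_sites(seq: str, circular: bool = False) -> int:
    """Number of BstXI sites (the pattern is its own reverse complement)."""
    probe = seq + seq[:11] if circular else seq
    return sum(1 for _ in BSTXI_REGEX.finditer(probe))


# ---------------------------------------------------------------------------
# feature cassette
# ---------------------------------------------------------------------------


@dataclass
class FeatureCassette:
    """Constant part of the SIC, written tag-end first, direct-repeat last.

    ``landmarks`` maps segment names to half-open intervals on ``sequence``;
    required names: ``tag_cds`` (linker+tag+stop), ``marker``,
    ``pol3_promoter``, ``direct_repeat``, ``anchor`` (constant 3' tail used
    by the junction-enrichment PCR).
    """

    sequence: str
    landmarks: dict[str, tuple[int, int]]
    overlap_len: int = 25

    def __post_init__(self) -> None:
        if count_bstxi_sites(self.sequence) != 0:
            raise AssemblyError("feature cassette must not contain a BstXI site")
        dr = self.landmarks["direct_repeat"]
        if dr[1] != len(self.sequence):
            raise AssemblyError("direct repeat must abut the promoter-side end")
        if self.landmarks["tag_cds"][0] != 0:
            raise AssemblyError("tag linker must abut the tag-side end")

    @property
    def overlap_tag_end(self) -> str:
        """Terminal segment on the tag side (oligo ``overlap_B``)."""
        return self.sequence[: self.overlap_len]

    @property
    def overlap_dr_end(self) -> str:
        """Terminal segment on the direct-repeat side (oligo ``overlap_A``)."""
        return self.sequence[-self.overlap_len :]

    def segment(self, name: str) -> str:
        s, e = self.landmarks[name]
        return self.sequence[s:e]


_NONSTOP_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in STOP_CODONS
]


def synthetic_cassette(
    seed: int = 7,
    tag_codons: int = 60,
    marker_codons: int = 50,
    promoter_len: int = 60,
    overlap_len: int = 25,
) -> FeatureCassette:
    """Deterministic synthetic feature cassette for simulation and tests.

    Emulates the layout of a tagging cassette (linker+fluorophore CDS,
    selection marker, Pol III promoter, Cas12a direct repeat) with random
    but reproducible filler coding/promoter sequence, guaranteed free of
    BstXI sites.
    """
    rng = np.random.default_rng(seed)
    for _ in range(100):
        linker = "GGTGCAGGCGCA"
        tag = "".join(rng.choice(_NONSTOP_CODONS, size=tag_codons)) + "TAA"
        spacer1 = "".join(rng.choice(list("ACGT"), size=12))
        marker = "ATG" + "".join(rng.choice(_NONSTOP_CODONS, size=marker_codons)) + "TGA"
        spacer2 = "".join(rng.choice(list("ACGT"), size=12))
        promoter = "".join(rng.choice(list("ACGT"), size=promoter_len))
        seq = linker + tag + spacer1 + marker + spacer2 + promoter + DIRECT_REPEAT
        if count_bstxi_sites(seq) or "T" * 6 in seq:
            continue
        pos = 0
        landmarks = {}
        for name, part in [
            ("tag_cds", linker + tag),
            ("_spacer1", spacer1),
            ("marker", marker),
            ("_spacer2", spacer2),
            ("pol3_promoter", promoter),
            ("direct_repeat", DIRECT_REPEAT),
        ]:
            landmarks[name] = (pos, pos + len(part))
            pos += len(part)
        landmarks["anchor"] = (len(seq) - 30, len(seq))
        return FeatureCassette(seq, landmarks, overlap_len=overlap_len)
    raise AssemblyError("could not generate a BstXI-free cassette")


# ---------------------------------------------------------------------------
# oligo design
# ---------------------------------------------------------------------------

_SEGMENT_ORDER = (
    "overlap_A",
    "spacer",
    "terminator",
    "ha_down",
    "bstxi_site",
    "ha_up",
    "overlap_B",
)


@dataclass
class OligoDesign:
    """One microarray oligo with its ordered segment map."""

    design_id: str
    orf_id: str
    candidate: CandidateTarget
    segments: dict[str, str]  # keys follow _SEGMENT_ORDER

    @property
    def sequence(self) -> str:
        return "".join(self.segments[name] for name in _SEGMENT_ORDER)

    def __len__(self) -> int:
        return len(self.sequence)


def design_oligo(
    genome: AnnotatedGenome,
    candidate: CandidateTarget,
    cassette: FeatureCassette,
    rules: DesignRules | None = None,
    terminator: str = DEFAULT_TERMINATOR,
    bstxi_site: str = DEFAULT_BSTXI_SITE,
) -> OligoDesign:
    """Build the oligo for one candidate target.

    ``ha_up`` ends immediately 5' of the insertion point (a codon boundary,
    since insertion is at the first STOP base); ``ha_down`` starts at the
    native STOP codon, which is retained downstream of the cassette.  Arm
    lengths are balanced so the total length hits the midpoint of the
    configured budget.
    """
    rules = rules or DesignRules()
    orf = genome.orf(candidate.orf_id)
    chrom = genome.chromosomes[orf.chrom]
    ins = insertion_point(genome, candidate.orf_id)

    fixed = (
        2 * cassette.overlap_len + len(candidate.spacer) + len(terminator) + len(bstxi_site)
    )
    target_total = (rules.oligo_len_min + rules.oligo_len_max) // 2
    arm_total = target_total - fixed
    len_up = arm_total // 2
    len_down = arm_total - len_up
    if min(len_up, len_down) < rules.min_arm:
        raise AssemblyError(
            f"length budget infeasible: arms {len_up}/{len_down} < {rules.min_arm}"
        )

    if orf.strand == "+":
        up_iv, down_iv = (ins - len_up, ins), (ins, ins + len_down)
    else:
        up_iv, down_iv = (ins, ins + len_up), (ins - len_down, ins)
    for name, (lo, hi) in (("ha_up", up_iv), ("ha_down", down_iv)):
        if lo < 0 or hi > len(chrom):
            raise AssemblyError(f"{name} extends past chromosome end")
        if "N" in chrom[lo:hi]:
            raise AssemblyError(f"{name} overlaps undefined (N) bases")
    ha_up = chrom[up_iv[0] : up_iv[1]]
    ha_down = chrom[down_iv[0] : down_iv[1]]
    if orf.strand == "-":
        ha_up, ha_down = revcomp(ha_up), revcomp(ha_down)

    segments = {
        "overlap_A": cassette.overlap_dr_end,
        "spacer": candidate.spacer,
        "terminator": terminator,
        "ha_down": ha_down,
        "bstxi_site": bstxi_site,
        "ha_up": ha_up,
        "overlap_B": cassette.overlap_tag_end,
    }
    oligo = OligoDesign(
        design_id=f"{candidate.orf_id}:{candidate.start}{candidate.strand_vs_genome}",
        orf_id=candidate.orf_id,
        candidate=candidate,
        segments=segments,
    )
    seq = oligo.sequence
    if not rules.oligo_len_min <= len(seq) <= rules.oligo_len_max:
        raise AssemblyError(f"oligo length {len(seq)} outside budget")
    if count_bstxi_sites(seq) != 1:
        raise AssemblyError("oligo must contain exactly one BstXI site")
    return oligo


def design_pool(
    genome: AnnotatedGenome,
    selected: dict[str, list[CandidateTarget]],
    cassette: FeatureCassette,
    rules: DesignRules | None = None,
    per_orf: int | None = 1,
) -> tuple[list[OligoDesign], dict[str, str]]:
    """Design oligos for a ranked candidate selection.

    Walks each ORF's candidates in rank order, skipping ones that cannot be
    laid out (arms over chromosome ends or N bases, accidental BstXI sites),
    keeping up to ``per_orf`` designs per ORF (None = all designable).
    Returns the designs plus a per-ORF failure reason for ORFs where no
    candidate was designable.
    """
    rules = rules or DesignRules()
    designs: list[OligoDesign] = []
    failures: dict[str, str] = {}
    for orf_id, cands in selected.items():
        kept = 0
        last_err = "no candidates"
        for cand in cands:
            try:
                designs.append(design_oligo(genome, cand, cassette, rules))
            except AssemblyError as exc:
                last_err = str(exc)
                continue
            kept += 1
            if per_orf is not None and kept >= per_orf:
                break
        if kept == 0:
            failures[orf_id] = last_err
    return designs, failures


# ---------------------------------------------------------------------------
# recombineering
# ---------------------------------------------------------------------------


@dataclass
class Circle:
    """Circular oligo+cassette intermediate, stored linearly from the
    cassette tag end (the declared origin)."""

    sequence: str
    cassette_len: int
    oligo_core_len: int  # oligo minus both overlaps


def assemble_circle(
    oligo: OligoDesign | str,
    cassette: FeatureCassette,
    min_overlap: int | None = None,
) -> Circle:
    """Join one oligo and one cassette into the circular intermediate.

    The oligo's terminal segments must match the cassette's terminal
    segments exactly over at least ``min_overlap`` bases; any substitution
    aborts assembly, mirroring the junction-fidelity selection of the
    overlap-assembly chemistry.
    """
    seq = oligo if isinstance(oligo, str) else oligo.sequence
    n = cassette.overlap_len if min_overlap is None else min_overlap
    if seq[:n] != cassette.sequence[-n:]:
        raise AssemblyError("overlap_A does not match the cassette DR end")
    if seq[-n:] != cassette.sequence[:n]:
        raise AssemblyError("overlap_B does not match the cassette tag end")
    circle = cassette.sequence + seq[n:-n]
    return Circle(circle, cassette_len=len(cassette.sequence), oligo_core_len=len(seq) - 2 * n)


@dataclass
class SIC:
    """A released self-integrating cassette (linear, ORF orientation)."""

    sequence: str
    residual_left: int  # bases preceding ha_up (from the cut site)
    residual_right: int  # bases following ha_down
    ha_up: str
    ha_down: str
    orf_id: str | None = None
    design_id: str | None = None
    spacer: str | None = None
    site_sequence: str | None = None  # PAM+protospacer of the designed target
    chrom: str | None = None
    strand: str = "+"

    @property
    def core(self) -> str:
        """Sequence without terminal residuals: ha_up + payload + ha_down."""
        end = len(self.sequence) - self.residual_right
        return self.sequence[self.residual_left : end]

    @property
    def payload(self) -> str:
        core = self.core
        return core[len(self.ha_up) : len(core) - len(self.ha_down)]


def rca_release(
    circle: Circle,
    n_copies: int,
    oligo: OligoDesign | None = None,
) -> list[SIC]:
    """Rolling-circle amplification followed by BstXI release.

    The concatemer is the circle repeated ``n_copies`` times; cutting at the
    centre of every BstXI site yields ``n_copies - 1`` identical full-length
    SICs plus two discarded terminal fragments.
    """
    if n_copies < 2:
        raise AssemblyError("RCA needs at least 2 copies to release a full SIC")
    n_sites = count_bstxi_sites(circle.sequence, circular=True)
    if n_sites == 0:
        raise AssemblyError("circle contains no BstXI site; SICs cannot be released")
    if n_sites > 1:
        raise AssemblyError("circle contains multiple BstXI sites (chimera guard)")

    concatemer = circle.sequence * n_copies
    cuts = [m.start(1) + 6 for m in BSTXI_REGEX.finditer(concatemer)]
    fragments = [concatemer[a:b] for a, b in zip(cuts[:-1], cuts[1:])]
    assert len(fragments) == n_copies - 1
    assert len(set(fragments)) <= 1

    meta: dict = {}
    ha_up = ha_down = ""
    if oligo is not None:
        ha_up, ha_down = oligo.segments["ha_up"], oligo.segments["ha_down"]
        cand = oligo.candidate
        meta = dict(
            orf_id=oligo.orf_id,
            design_id=oligo.design_id,
            spacer=oligo.segments["spacer"],
            site_sequence=cand.site_sequence if cand is not None else None,
            chrom=cand.chrom if cand is not None else None,
        )
    return [
        SIC(
            sequence=frag,
            residual_left=6,
            residual_right=6,
            ha_up=ha_up,
            ha_down=ha_down,
            **meta,
        )
        for frag in fragments
    ]


# ---------------------------------------------------------------------------
# genomic integration
# ---------------------------------------------------------------------------


@dataclass
class IntegrationReport:
    success: bool
    in_frame: bool = False
    target_destroyed: bool = False
    edited_locus: str = ""
    junction_5p: str = ""
    junction_3p: str = ""
    failure_reason: str | None = None
    edited_chrom: str | None = None
    replaced_span: tuple[int, int] | None = None
    insert_delta: int = 0

    def __post_init__(self) -> None:
        if self.in_frame and not self.success:
            raise ValueError("in_frame implies success")


def _locate_unique(arm: str, chrom: str, max_edits: int) -> tuple[int, int] | None:
    res = edlib.align(arm, chrom, mode="HW", task="locations", k=max_edits)
    if res["editDistance"] < 0:
        return None
    locs = res["locations"]
    starts = {s for s, _ in locs}
    if len(starts) > 1 and max(starts) - min(starts) > max_edits:
        return None  # ambiguous / ectopic
    s, e = locs[0]
    return s, e + 1


def simulate_integration(
    genome: AnnotatedGenome,
    sic: SIC,
    cassette: FeatureCassette,
    orf: OrfRecord | None = None,
    min_arm_match: int = 28,
    max_arm_edits: int = 3,
    max_gap: int = 20,
) -> tuple[IntegrationReport, AnnotatedGenome]:
    """Simulate homologous recombination of one SIC into the genome.

    Terminal cut-site residuals are ignored (end resection).  Both homology
    arms are located in the target chromosome by approximate matching (at
    most ``max_arm_edits`` edits each — the repair machinery tolerates small
    heterologies, which are then *copied into the genome*, the origin of
    frameshifted dark clones).  The genomic span between the arm matches is
    replaced by the SIC core.

    ``in_frame`` is True when the fusion ORF translates from the native
    START through the tag CDS without premature STOP and with the tag in
    frame; ``target_destroyed`` reports whether the designed PAM+protospacer
    still occurs at the edited locus.
    """
    if orf is None:
        if sic.orf_id is None:
            raise ValueError("need an OrfRecord or a SIC with orf_id")
        orf = genome.orf(sic.orf_id)
    if min(len(sic.ha_up), len(sic.ha_down)) < min_arm_match:
        raise ValueError(f"homology arms must be >= {min_arm_match} bp")
    chrom = genome.chromosomes[orf.chrom]

    # orient the SIC core to the forward genomic strand
    core = sic.core
    if orf.strand == "+":
        core_f, lead, trail = core, sic.ha_up, sic.ha_down
    else:
        core_f, lead, trail = revcomp(core), revcomp(sic.ha_down), revcomp(sic.ha_up)

    fail = None
    loc_lead = _locate_unique(lead, chrom, max_arm_edits)
    loc_trail = _locate_unique(trail, chrom, max_arm_edits)
    if loc_lead is None:
        fail = "5' homology arm not found at a unique locus"
    elif loc_trail is None:
        fail = "3' homology arm not found at a unique locus"
    elif not (0 <= loc_trail[0] - loc_lead[1] <= max_gap) and not (
        0 <= loc_lead[1] - loc_trail[0] <= max_arm_edits
    ):
        fail = "homology arms do not flank a common locus"
    if fail:
        return IntegrationReport(success=False, failure_reason=fail), genome

    a_start, b_end = loc_lead[0], loc_trail[1]
    edited = chrom[:a_start] + core_f + chrom[b_end:]
    delta = len(core_f) - (b_end - a_start)

    # reading-frame check: locate the constant tag CDS and count codons
    tag_cds = cassette.segment("tag_cds")
    oriented = edited if orf.strand == "+" else revcomp(edited)
    if orf.strand == "+":
        o_cds = orf.cds_start
    else:
        o_cds = len(edited) - (orf.cds_end + delta)
    t = oriented.find(tag_cds, o_cds)
    in_frame = False
    if 0 <= o_cds and t >= 0:
        if (t - o_cds) % 3 == 0:
            stop = first_stop_codon(oriented[o_cds : t + len(tag_cds)])
            in_frame = stop is not None and stop == (t + len(tag_cds) - 3 - o_cds) // 3

    destroyed = True
    if sic.site_sequence:
        lo = max(a_start - 200, 0)
        hi = min(a_start + len(core_f) + 200, len(edited))
        locus = edited[lo:hi]
        destroyed = (
            sic.site_sequence not in locus and sic.site_sequence not in revcomp(locus)
        )

    report = IntegrationReport(
        success=True,
        in_frame=in_frame,
        target_destroyed=destroyed,
        edited_locus=edited[max(a_start - 50, 0) : a_start + len(core_f) + 50],
        junction_5p=edited[max(a_start - 20, 0) : a_start + 20],
        junction_3p=edited[a_start + len(core_f) - 20 : a_start + len(core_f) + 20],
        edited_chrom=orf.chrom,
        replaced_span=(a_start, b_end),
        insert_delta=delta,
    )

    # build the edited genome, shifting/dropping ORFs on the edited chromosome
    new_chroms = dict(genome.chromosomes)
    new_chroms[orf.chrom] = edited
    new_orfs = []
    for o in genome.orfs:
        if o.chrom != orf.chrom:
            new_orfs.append(o)
            continue
        if o.cds_end <= a_start:
            new_orfs.append(o)
        elif o.cds_start >= b_end:
            new_orfs.append(
                OrfRecord(
                    o.orf_id,
                    o.chrom,
                    o.strand,
                    o.cds_start + delta,
                    o.cds_end + delta,
                    o.stop_codon_start + delta,
                )
            )
        # ORFs overlapping the replaced span (incl. the target) are dropped
    edited_genome = AnnotatedGenome(new_chroms, new_orfs)
    return report, edited_genome
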