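"""Cas12a target enumeration, filtering and ranking near ORF C-termini.

Candidate protospacers are enumerated on both genomic strands wherever a
T-rich PAM (TTV, V ∈ {A,C,G}, or TYN, Y ∈ {C,T}) lies immediately 5' of a
spacer-length protospacer whose extent overlaps the terminus window of an
ORF.  Candidates are then annotated with the features known to affect
tagging success — PAM class (TTC > TTG > TTA >> TYN), PAM-proximal
dinucleotide (CG/CC/GG favourable), whether the target survives cassette
insertion (recurrent cleavage), strandedness relative to transcription —
filtered for Pol III terminator-like T-runs and off-target seed matches,
and ranked by a multiplicative score.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._seq import revcomp
from .genome import AnnotatedGenome, terminus_window

#: 3' tail of the Cas12a direct repeat as it abuts the spacer in the
#: integrated cassette; ends in GAT, which cannot complete a TTV/TYN PAM.
DR_TAIL = "TCTACTGTTGTAGAT"

#: Pol III terminator encoded downstream of the spacer on the oligo.
DEFAULT_TERMINATOR = "T" * 7

_PAM_REGEX = {
    "TTV": "TT[ACG]",
    "TYN": "T[CT][ACGT]",
}


@dataclass(frozen=True)
class CandidateTarget:
    """One Cas12a protospacer + PAM near an ORF terminus."""

    orf_id: str
    pam: str
    pam_class: str  # TTC | TTG | TTA | TYN_other
    spacer: str  # protospacer, PAM-proximal base first
    strand_vs_genome: str  # strand carrying PAM+protospacer
    targets_nontranscribed_strand: bool
    proximal_dinuc: str
    chrom: str
    start: int  # genomic interval of PAM+protospacer, forward strand
    end: int
    distance_to_insertion: int
    destroyed_by_insertion: bool = False
    off_target_hits: int = 0
    duplicate_target: bool = False
    t_run_fail: bool = False
    score: float = 1.0

    @property
    def site_sequence(self) -> str:
        """Contiguous PAM+protospacer string in its own strand orientation."""
        return self.pam + self.spacer


@dataclass
class DesignRules:
    """Constants of the design rule set; defaults follow the published rules."""

    pam_patterns: tuple[str, ...] = ("TTV", "TYN")
    spacer_len: int = 20
    flank: int = 30
    max_t_run: int = 5
    off_target_max_seed_hits: int = 10
    off_target_seed_len: int = 10
    forbid_perfect_duplicates: bool = True
    require_destruction: bool = False
    max_candidates_per_orf: int = 7
    # multiplicative score weights
    w_pam: dict = field(
        default_factory=lambda: {"TTC": 3.0, "TTG": 2.0, "TTA": 1.5, "TYN_other": 1.0}
    )
    w_dinuc: float = 2.5
    favorable_dinucs: tuple[str, ...] = ("CG", "CC", "GG")
    w_destroy: float = 3.5
    w_strand: float = 1.5
    # oligo layout constants (shared with assembly)
    oligo_len_min: int = 160
    oligo_len_max: int = 170
    min_arm: int = 29

    def __post_init__(self) -> None:
        if self.spacer_len <= 0 or self.flank < 0 or self.off_target_seed_len <= 0:
            raise ValueError("lengths must be positive")
        if any(w <= 0 for w in self.w_pam.values()):
            raise ValueError("weights must be positive")
        for pat in self.pam_patterns:
            if pat not in _PAM_REGEX:
                raise ValueError(f"unknown PAM pattern {pat}")

    @property
    def pam_regex(self) -> str:
        return "(?:" + "|".join(_PAM_REGEX[p] for p in self.pam_patterns) + ")"


def classify_pam(pam: str) -> str:
    """PAM class with TTV classes taking precedence over the TYN catch-all."""
    return pam if pam in ("TTC", "TTG", "TTA") else "TYN_other"


def insertion_point(genome: AnnotatedGenome, orf_id: str) -> int:
    """Genomic gap coordinate where the cassette payload is inserted.

    The payload goes immediately 5' of the STOP codon in ORF orientation:
    before ``stop_codon_start`` for plus-strand ORFs, after the codon for
    minus-strand ORFs.
    """
    orf = genome.orf(orf_id)
    return orf.stop_codon_start if orf.strand == "+" else orf.stop_codon_start + 3


def scan_candidates(
    genome: AnnotatedGenome, orf_id: str, rules: DesignRules | None = None
) -> list[CandidateTarget]:
    """Enumerate all PAM+protospacer sites overlapping the terminus window."""
    rules = rules or DesignRules()
    orf = genome.orf(orf_id)
    win = terminus_window(genome, orf_id, rules.flank)
    chrom = genome.chromosomes[orf.chrom]
    wlo = orf.stop_codon_start - rules.flank
    whi = orf.stop_codon_start + 3 + rules.flank
    wlo, whi = max(wlo, 0), min(whi, len(chrom))

    # region large enough to hold any PAM+protospacer whose spacer overlaps it
    pad = rules.spacer_len + 3
    rlo, rhi = max(wlo - pad, 0), min(whi + pad, len(chrom))
    region = chrom[rlo:rhi]
    pam_re = re.compile("(?=(" + rules.pam_regex + "))")
    L = rules.spacer_len
    ins = insertion_point(genome, orf_id)

    out: list[CandidateTarget] = []
    for strand, seq in (("+", region), ("-", revcomp(region))):
        for m in pam_re.finditer(seq):
            i = m.start()
            if i + 3 + L > len(seq):
                continue
            pam = seq[i : i + 3]
            spacer = seq[i + 3 : i + 3 + L]
            if "N" in pam or "N" in spacer:
                continue
            if strand == "+":
                g_start = rlo + i
                ps, pe = g_start + 3, g_start + 3 + L
                g_end = pe
            else:
                g_end = rhi - i
                g_start = g_end - 3 - L
                ps, pe = g_start, g_start + L
            if g_start < 0 or g_end > len(chrom):
                continue
            # protospacer must overlap the terminus window
            if pe <= wlo or ps >= whi:
                continue
            dist = (ps - ins) if orf.strand == "+" else (ins - pe)
            out.append(
                CandidateTarget(
                    orf_id=orf_id,
                    pam=pam,
                    pam_class=classify_pam(pam),
                    spacer=spacer,
                    strand_vs_genome=strand,
                    targets_nontranscribed_strand=(strand == orf.strand),
                    proximal_dinuc=spacer[:2],
                    chrom=orf.chrom,
                    start=g_start,
                    end=g_end,
                    distance_to_insertion=dist,
                )
            )
    if win.clipped:
        out = [c for c in out if c.start >= 0 and c.end <= len(chrom)]
    out.sort(key=lambda c: (c.start, c.strand_vs_genome))
    return out


def t_run_filter(candidate: CandidateTarget, rules: DesignRules | None = None) -> bool:
    """True iff the spacer contains a run of more than ``max_t_run`` T's.

    Such runs act as premature Pol III terminators within the crRNA gene.
    """
    rules = rules or DesignRules()
    return re.search("T{%d,}" % (rules.max_t_run + 1), candidate.spacer) is not None


def off_target_estimate(
    candidate: CandidateTarget, genome: AnnotatedGenome, rules: DesignRules | None = None
) -> tuple[int, bool]:
    """Count PAM-adjacent perfect seed matches elsewhere in the genome.

    Returns ``(seed_hits, duplicate)`` where ``seed_hits`` is the number of
    genomic sites other than the intended one carrying a configured PAM
    immediately 5' of a perfect match of the PAM-proximal seed
    (``off_target_seed_len`` bases), and ``duplicate`` is True when the full
    PAM+protospacer occurs perfectly at another site.
    """
    rules = rules or DesignRules()
    seed = candidate.spacer[: rules.off_target_seed_len]
    seed_re = re.compile("(?=" + rules.pam_regex + re.escape(seed) + ")")
    full = candidate.site_sequence
    full_re = re.compile("(?=" + re.escape(full) + ")")

    seed_hits = 0
    full_hits = 0
    for seq in genome.chromosomes.values():
        for s in (seq, revcomp(seq)):
            seed_hits += sum(1 for _ in seed_re.finditer(s))
            full_hits += sum(1 for _ in full_re.finditer(s))
    # the intended site matches both patterns by construction
    return max(seed_hits - 1, 0), full_hits > 1


def _default_check_payload(spacer: str) -> str:
    """Minimal stand-in for the integrated cassette around the crRNA gene.

    Only the direct-repeat/spacer junction of the payload can plausibly
    recreate a PAM+protospacer, so the generic cassette body is irrelevant
    for the destruction check.
    """
    return "GCCAGGTCCTGCAGGACCTGGC" + DR_TAIL + spacer + DEFAULT_TERMINATOR


def destruction_check(
    genome: AnnotatedGenome,
    candidate: CandidateTarget,
    payload: str | None = None,
    ins: int | None = None,
    locus_pad: int = 200,
) -> bool:
    """True (destroyed) iff PAM+protospacer vanishes from the edited locus.

    The edited locus is modelled by inserting the cassette payload (in ORF
    orientation) at the insertion point; the contiguous PAM+protospacer is
    then searched on both strands of the surrounding region.
    """
    if ins is None:
        ins = insertion_point(genome, candidate.orf_id)
    if payload is None:
        payload = _default_check_payload(candidate.spacer)
    orf = genome.orf(candidate.orf_id)
    chrom = genome.chromosomes[orf.chrom]
    payload_fwd = payload if orf.strand == "+" else revcomp(payload)
    lo = max(ins - locus_pad, 0)
    hi = min(ins + locus_pad, len(chrom))
    edited = chrom[lo:ins] + payload_fwd + chrom[ins:hi]
    site = candidate.site_sequence
    return site not in edited and site not in revcomp(edited)


def score_candidate(candidate: CandidateTarget, rules: DesignRules | None = None) -> float:
    """Multiplicative efficiency score from the published feature effects."""
    rules = rules or DesignRules()
    score = rules.w_pam[candidate.pam_class]
    if candidate.proximal_dinuc in rules.favorable_dinucs:
        score *= rules.w_dinuc
    if candidate.destroyed_by_insertion:
        score *= rules.w_destroy
    if candidate.targets_nontranscribed_strand:
        score *= rules.w_strand
    return score


def annotate_candidate(
    candidate: CandidateTarget,
    genome: AnnotatedGenome,
    rules: DesignRules | None = None,
    payload: str | None = None,
) -> CandidateTarget:
    """Compute all filter flags and the score for a scanned candidate."""
    rules = rules or DesignRules()
    hits, dup = off_target_estimate(candidate, genome, rules)
    cand = replace(
        candidate,
        t_run_fail=t_run_filter(candidate, rules),
        off_target_hits=hits,
        duplicate_target=dup,
        destroyed_by_insertion=destruction_check(genome, candidate, payload=payload),
    )
    return replace(cand, score=score_candidate(cand, rules))


def passes_filters(candidate: CandidateTarget, rules: DesignRules) -> bool:
    if candidate.t_run_fail:
        return False
    if candidate.off_target_hits > rules.off_target_max_seed_hits:
        return False
    if rules.forbid_perfect_duplicates and candidate.duplicate_target:
        return False
    if rules.require_destruction and not candidate.destroyed_by_insertion:
        return False
    return True


_TABLE_COLUMNS = [
    "orf_id",
    "chrom",
    "strand",
    "pam",
    "pam_class",
    "spacer",
    "start",
    "end",
    "distance_to_insertion",
    "proximal_dinuc",
    "targets_nontranscribed_strand",
    "destroyed_by_insertion",
    "off_target_hits",
    "duplicate_target",
    "t_run_fail",
    "score",
]


def candidates_to_frame(candidates: list[CandidateTarget]) -> pd.DataFrame:
    rows = [
        {
            "orf_id": c.orf_id,
            "chrom": c.chrom,
            "strand": c.strand_vs_genome,
            "pam": c.pam,
            "pam_class": c.pam_class,
            "spacer": c.spacer,
            "start": c.start,
            "end": c.end,
            "distance_to_insertion": c.distance_to_insertion,
            "proximal_dinuc": c.proximal_dinuc,
            "targets_nontranscribed_strand": c.targets_nontranscribed_strand,
            "destroyed_by_insertion": c.destroyed_by_insertion,
            "off_target_hits": c.off_target_hits,
            "duplicate_target": c.duplicate_target,
            "t_run_fail": c.t_run_fail,
            "score": c.score,
        }
        for c in candidates
    ]
    return pd.DataFrame(rows, columns=_TABLE_COLUMNS)


def select_candidates(
    genome: AnnotatedGenome,
    rules: DesignRules | None = None,
    orf_ids: list[str] | None = None,
    payload: str | None = None,
    array_size: int | None = None,
    seed: int | None = None,
) -> tuple[dict[str, list[CandidateTarget]], list[str]]:
    """Per-ORF filtered, ranked (and optionally capped) candidate selection.

    Survivors are ordered by descending score, then by absolute distance to
    the insertion point, then genomic coordinate/strand — a deterministic
    total order.  When ``array_size`` caps the pooled design globally, a
    seeded uniform draw over all surviving candidates is taken (mirroring a
    random fill of a fixed-size microarray).

    Returns ``(per-ORF selected candidates, undesignable ORF ids)``.
    """
    rules = rules or DesignRules()
    orf_ids = orf_ids if orf_ids is not None else genome.orf_ids

    selected: dict[str, list[CandidateTarget]] = {}
    undesignable: list[str] = []
    for orf_id in orf_ids:
        cands = [
            annotate_candidate(c, genome, rules, payload=payload)
            for c in scan_candidates(genome, orf_id, rules)
        ]
        survivors = [c for c in cands if passes_filters(c, rules)]
        survivors.sort(
            key=lambda c: (
                -c.score,
                abs(c.distance_to_insertion),
                c.start,
                c.strand_vs_genome,
            )
        )
        survivors = survivors[: rules.max_candidates_per_orf]
        if survivors:
            selected[orf_id] = survivors
        else:
            undesignable.append(orf_id)

    if array_size is not None:
        flat = [(orf_id, c) for orf_id in selected for c in selected[orf_id]]
        if len(flat) > array_size:
            rng = np.random.default_rng(seed)
            keep = rng.choice(len(flat), size=array_size, replace=False)
            kept = [flat[i] for i in sorted(keep)]
            selected = {}
            for orf_id, c in kept:
                selected.setdefault(orf_id, []).append(c)
    return selected, undesignable
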