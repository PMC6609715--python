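"""Junction-read quantification: from paired reads to UMI-deduplicated
genotype × sample count matrices.

The counting contract follows targeted junction-enrichment sequencing of
pooled tag libraries: a read pair is counted for a design only when both
mates match that design's junction reference, the forward mate's match
starts at reference position 0 (the constant cassette region), and the
inferred insert size exceeds the span provided as homology during tagging —
so that free, non-integrated cassettes never count as genomic insertions.
UMIs are collapsed with the directional rule (merge a lower-count UMI into a
Hamming-distance-1 neighbour when ``count(u) >= 2*count(v) - 1``).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import edlib
import pandas as pd

from ._seq import revcomp
from .assembly import FeatureCassette, OligoDesign
from .genome import AnnotatedGenome
from .targets import DEFAULT_TERMINATOR, insertion_point


def levenshtein(a: str, b: str) -> int:
    return edlib.align(a, b, mode="NW", task="distance")["editDistance"]


# ---------------------------------------------------------------------------
# junction references
# ---------------------------------------------------------------------------


@dataclass
class JunctionReference:
    """Per-design reference: constant cassette tail + proximal genomic DNA."""

    design_id: str
    orf_id: str
    sequence: str
    homology_len: int  # prefix also present on the free (unintegrated) SIC

    def __post_init__(self) -> None:
        if len(self.sequence) <= self.homology_len:
            raise ValueError("reference must extend beyond the homology span")


def build_junction_references(
    designs: list[OligoDesign],
    cassette: FeatureCassette,
    genome: AnnotatedGenome,
    genomic_len: int = 600,
    anchor_len: int = 30,
    terminator: str = DEFAULT_TERMINATOR,
) -> dict[str, JunctionReference]:
    """Assemble the expected junction sequence for every design.

    Reference = cassette anchor (constant tail) + spacer + Pol III
    terminator + ``genomic_len`` bases of proximal genomic sequence in ORF
    orientation starting at the insertion point (the first ``len(ha_down)``
    of which are the 3' homology arm).
    """
    refs: dict[str, JunctionReference] = {}
    anchor = cassette.sequence[-anchor_len:]
    for d in designs:
        orf = genome.orf(d.orf_id)
        chrom = genome.chromosomes[orf.chrom]
        ins = insertion_point(genome, d.orf_id)
        if orf.strand == "+":
            genomic = chrom[ins : ins + genomic_len]
        else:
            genomic = revcomp(chrom[max(ins - genomic_len, 0) : ins])
        seq = anchor + d.segments["spacer"] + terminator + genomic
        hom = anchor_len + len(d.segments["spacer"]) + len(terminator) + len(
            d.segments["ha_down"]
        )
        refs[d.design_id] = JunctionReference(d.design_id, d.orf_id, seq, hom)
    return refs


# ---------------------------------------------------------------------------
# demultiplexing and feature extraction
# ---------------------------------------------------------------------------


def validate_barcode_set(barcodes: dict[str, str], min_distance: int = 3) -> None:
    names = list(barcodes)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            d = levenshtein(barcodes[a], barcodes[b])
            if d < min_distance:
                raise ValueError(
                    f"barcodes {a}/{b} at Levenshtein distance {d} < {min_distance}"
                )


def demux_barcodes(observed: str, barcodes: dict[str, str], validate: bool = True) -> str | None:
    """Assign a barcode read to the unique sample within edit distance 1."""
    if validate:
        validate_barcode_set(barcodes)
    hits = [s for s, bc in barcodes.items() if levenshtein(observed, bc) <= 1]
    return hits[0] if len(hits) == 1 else None


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def extract_features(read1: str, read2: str, adapter: "AdapterSpec") -> dict:
    """Slice UMI, barcode and junction segments from a read pair.

    Constant anchors are verified at their declared offsets with at most one
    mismatch each; pairs failing an anchor are rejected with a reason.
    Returns a dict with ``ok`` plus, on success, ``umi``, ``barcode``,
    ``junction1`` (mate 1, starts at the constant cassette region) and
    ``junction2`` (mate 2 with the adapter removed).
    """
    a1 = adapter.r1_anchor
    if _hamming(read1[: len(a1)], a1) > 1:
        return {"ok": False, "reason": "r1_anchor_missing"}
    off = adapter.barcode_len + adapter.umi_len
    a2 = adapter.r2_anchor
    if _hamming(read2[off : off + len(a2)], a2) > 1:
        return {"ok": False, "reason": "r2_anchor_missing"}
    return {
        "ok": True,
        "barcode": read2[: adapter.barcode_len],
        "umi": read2[adapter.barcode_len : off],
        "junction1": read1,
        "junction2": read2[off + len(a2) :],
    }


# imported late to avoid a cycle in the module graph
from .simulate import AdapterSpec  # noqa: E402,F401


# ---------------------------------------------------------------------------
# read-pair matching and counting
# ---------------------------------------------------------------------------


class ReadMatcher:
    """Seed-and-extend matcher of reads against junction references.

    Exact ``seed_len``-mer lookup (several read offsets are tried, so one
    sequencing error cannot mask a molecule) followed by mismatch-counting
    extension over the full read/reference overlap.  An external SAM stream
    may substitute for this matcher downstream; the counting rules only need
    (reference, start, mismatches) per mate.
    """

    def __init__(
        self,
        references: dict[str, JunctionReference],
        seed_len: int = 20,
        seed_step: int = 10,
        max_mismatches: int = 4,
    ):
        self.references = references
        self.seed_len = seed_len
        self.seed_step = seed_step
        self.max_mismatches = max_mismatches
        self.index: dict[str, list[tuple[str, int]]] = {}
        for rid, ref in references.items():
            s = ref.sequence
            for i in range(len(s) - seed_len + 1):
                self.index.setdefault(s[i : i + seed_len], []).append((rid, i))

    def match(self, read: str, within: str | None = None) -> tuple[str, int, int] | None:
        """Best (reference_id, read start on reference, mismatches) or None.

        Ties between different references are ambiguous and return None.
        ``within`` restricts the search to one reference (concordant
        placement of the second mate of an already-assigned pair).
        """
        k, step = self.seed_len, self.seed_step
        candidates: set[tuple[str, int]] = set()
        for off in range(0, max(len(read) - k, 0) + 1, step):
            for rid, pos in self.index.get(read[off : off + k], ()):
                if within is None or rid == within:
                    candidates.add((rid, pos - off))
        best: tuple[int, str, int] | None = None
        tie = False
        for rid, start in candidates:
            if start < 0:
                continue
            ref = self.references[rid].sequence
            seg = ref[start : start + len(read)]
            if len(seg) < min(len(read), k):
                continue
            mm = _hamming(read[: len(seg)], seg)
            if mm > self.max_mismatches:
                continue
            if best is None or mm < best[0]:
                best, tie = (mm, rid, start), False
            elif mm == best[0] and rid != best[1]:
                tie = True
        if best is None or tie:
            return None
        return best[1], best[2], best[0]


def count_insertions(
    pairs: pd.DataFrame,
    references: dict[str, JunctionReference],
    adapter: "AdapterSpec | None" = None,
    matcher: ReadMatcher | None = None,
    barcodes: dict[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the pair-counting rules to junction read pairs.

    ``pairs`` needs columns ``pair_id``, ``read1``, ``read2`` (raw mate 2
    when ``adapter`` is given, otherwise already adapter-stripped) and
    optionally ``sample``.  A pair is counted for design g iff both mates
    match reference g, mate 1 starts at reference position 0, and the
    inferred insert size exceeds the homology span of g.

    Returns ``(counts, assignments)``: pre-deduplication counts per
    (sample, design) and the per-pair assignment table.
    """
    matcher = matcher or ReadMatcher(references)
    if barcodes is not None:
        validate_barcode_set(barcodes)
    rows = []
    for tup in pairs.itertuples(index=False):
        d = tup._asdict()
        umi, sample = d.get("umi", ""), d.get("sample", "")
        r1, r2 = d["read1"], d["read2"]
        if adapter is not None:
            feats = extract_features(r1, r2, adapter)
            if not feats["ok"]:
                rows.append(
                    {
                        "pair_id": d["pair_id"],
                        "sample": sample,
                        "genotype": None,
                        "counted": False,
                        "reason": feats["reason"],
                        "umi": "",
                        "insert_size": -1,
                    }
                )
                continue
            r1, r2, umi = feats["junction1"], feats["junction2"], feats["umi"]
            if barcodes is not None:
                sample = demux_barcodes(feats["barcode"], barcodes, validate=False)
                if sample is None:
                    rows.append(
                        {
                            "pair_id": d["pair_id"],
                            "sample": "",
                            "genotype": None,
                            "counted": False,
                            "reason": "barcode_unassigned",
                            "umi": umi,
                            "insert_size": -1,
                        }
                    )
                    continue
        m1 = matcher.match(r1)
        # the reverse mate is placed concordantly on the forward mate's
        # reference (paired-end alignment); a mate that fits nowhere on that
        # reference rejects the pair
        m2 = matcher.match(revcomp(r2), within=m1[0]) if m1 else None
        reason, genotype, insert = None, None, -1
        if m1 is None or m2 is None:
            reason = "unmatched_mate"
        elif m1[1] != 0:
            reason = "forward_not_at_constant_region"
        else:
            genotype = m1[0]
            insert = m2[1] + len(r2)
            if insert <= references[genotype].homology_len:
                reason, genotype = "insert_within_homology", None
        rows.append(
            {
                "pair_id": d["pair_id"],
                "sample": sample,
                "genotype": genotype,
                "counted": genotype is not None,
                "reason": reason,
                "umi": umi,
                "insert_size": insert,
            }
        )
    assignments = pd.DataFrame(rows)
    counted = assignments[assignments.counted]
    counts = (
        counted.groupby(["sample", "genotype"]).size().rename("reads").reset_index()
    )
    return counts, assignments


# ---------------------------------------------------------------------------
# UMI deduplication (directional rule)
# ---------------------------------------------------------------------------


def dedup_umis(umis) -> int:
    """Collapse a UMI multiset into a molecule count.

    Directional clustering: UMIs are visited in descending count order; a
    UMI v merges into an accepted representative u when Hamming(u, v) = 1
    and ``count(u) >= 2 * count(v) - 1``.  Returns the number of cluster
    representatives.
    """
    counts = Counter(umis) if not isinstance(umis, Counter) else umis
    if not counts:
        return 0
    lengths = {len(u) for u in counts}
    if len(lengths) != 1:
        raise ValueError("UMIs must have equal length")
    reps: list[tuple[str, int]] = []
    for u, c in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])):
        merged = False
        for ru, rc in reps:
            if rc >= 2 * c - 1 and _hamming(ru, u) == 1:
                merged = True
                break
        if not merged:
            reps.append((u, c))
    return len(reps)


def dedup_count_matrix(assignments: pd.DataFrame) -> pd.DataFrame:
    """UMI-deduplicated molecule counts per (sample, genotype)."""
    counted = assignments[assignments.counted]
    rows = [
        {"sample": s, "genotype": g, "molecules": dedup_umis(grp.umi)}
        for (s, g), grp in counted.groupby(["sample", "genotype"])
    ]
    return pd.DataFrame(rows, columns=["sample", "genotype", "molecules"])


def to_count_matrix(long_counts: pd.DataFrame, value: str = "molecules") -> pd.DataFrame:
    """Pivot long-format counts to a genotype × sample integer matrix."""
    m = long_counts.pivot_table(
        index="genotype", columns="sample", values=value, fill_value=0, aggfunc="sum"
    )
    return m.astype(int)


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------


def classify_on_off_target(
    spacer_design: str,
    junction_design: str | None,
    experiment_designs: set[str] | None = None,
) -> str:
    """on_target / off_target call for one read or clone.

    ``off_target`` when the observed junction locus is not the one the
    spacer was designed for; a contaminant (a design foreign to the current
    experiment found at its own cognate locus) is on-target but flagged.
    """
    if junction_design is None or spacer_design != junction_design:
        return "off_target"
    if experiment_designs is not None and spacer_design not in experiment_designs:
        return "on_target_foreign_design"
    return "on_target"


def classify_molecules(
    molecules: pd.DataFrame | list[str],
    designs: dict[str, str],
    max_distance: int | None = None,
) -> pd.DataFrame:
    """Assign observed molecule sequences to the nearest design.

    Each molecule goes to the design minimizing global edit distance (ties
    -> unassigned); distance 0 molecules are error-free, others erroneous.
    Returns a per-design table with ``error_free``, ``erroneous`` and
    ``status`` (absent = zero assigned molecules).
    """
    if isinstance(molecules, pd.DataFrame):
        seqs = molecules["sequence"].tolist()
    else:
        seqs = list(molecules)
    ids = list(designs)
    tallies = {d: {"error_free": 0, "erroneous": 0} for d in ids}
    unassigned = 0
    for seq in seqs:
        dists = [levenshtein(seq, designs[d]) for d in ids]
        if max_distance is not None:
            dists = [d if d <= max_distance else 10**9 for d in dists]
        best = min(dists)
        if best >= 10**9 or dists.count(best) > 1:
            unassigned += 1
            continue
        d = ids[dists.index(best)]
        tallies[d]["error_free" if best == 0 else "erroneous"] += 1
    rows = []
    for d in ids:
        ef, er = tallies[d]["error_free"], tallies[d]["erroneous"]
        status = "absent" if ef + er == 0 else ("error_free" if ef else "erroneous")
        rows.append(
            {"design_id": d, "error_free": ef, "erroneous": er, "status": status}
        )
    out = pd.DataFrame(rows)
    out.attrs["unassigned"] = unassigned
    return out
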