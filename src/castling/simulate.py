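"""Synthetic-data generation for every downstream analysis.

The generators emulate the statistical structure of the real experiments:

* **random genomes** with plantable ORFs (fixtures for design/integration),
* **microarray oligo pools** with a positional error gradient — substitutions
  more frequent toward the 3' end (synthesized first), deletions toward the
  5' end — and log-normal per-design abundance,
* **pooled clone libraries** containing on-target, dark (frameshifted),
  off-target, contaminant and co-integrant clones at configurable rates,
* **paired junction-enrichment reads** with sample barcodes, UMIs, PCR
  duplication and optional uniform substitution errors,
* **FACS bin counts** for genotypes of known fluorescence intensity.

Every generator is deterministic under a fixed seed, and every emitted
molecule/clone/read is traceable to ground truth through the returned
annotation tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._seq import revcomp
from .assembly import OligoDesign
from .genome import AnnotatedGenome, OrfRecord

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_NONSTOP = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]


# ---------------------------------------------------------------------------
# fixture genomes
# ---------------------------------------------------------------------------


def random_genome(
    n_chroms: int = 2,
    chrom_len: int = 12_000,
    n_orfs: int = 10,
    seed: int = 0,
    orf_len_codons: tuple[int, int] = (60, 200),
    margin: int = 120,
) -> AnnotatedGenome:
    """Random genome with non-overlapping ORFs on both strands.

    ORFs are written into the random background as ATG + stop-free codons +
    STOP, oriented per a randomly drawn strand, and spaced so that homology
    arms and terminus windows never run off chromosome ends.
    """
    rng = np.random.default_rng(seed)
    chroms: dict[str, str] = {}
    orfs: list[OrfRecord] = []
    per_chrom = [n_orfs // n_chroms + (1 if i < n_orfs % n_chroms else 0) for i in range(n_chroms)]
    k = 0
    for ci in range(n_chroms):
        name = f"chr{ci + 1}"
        seq = rng.choice(_BASES, size=chrom_len).astype("U1")
        slots = per_chrom[ci]
        cursor = margin
        for _ in range(slots):
            n_codons = int(rng.integers(orf_len_codons[0], orf_len_codons[1] + 1))
            length = 3 * n_codons + 6  # ATG + body + STOP
            if cursor + length + margin > chrom_len:
                break
            strand = "+" if rng.random() < 0.5 else "-"
            body = "".join(rng.choice(_NONSTOP, size=n_codons))
            stop = str(rng.choice(["TAA", "TAG", "TGA"]))
            orf_seq = "ATG" + body + stop
            if strand == "-":
                orf_seq = revcomp(orf_seq)
            start = cursor
            end = start + length
            seq[start:end] = list(orf_seq)
            orfs.append(
                OrfRecord(
                    orf_id=f"ORF{k + 1:04d}",
                    chrom=name,
                    strand=strand,
                    cds_start=start,
                    cds_end=end,
                    stop_codon_start=(end - 3 if strand == "+" else start),
                )
            )
            k += 1
            cursor = end + margin
        chroms[name] = "".join(seq)
    return AnnotatedGenome(chroms, orfs)


# ---------------------------------------------------------------------------
# oligo pools with synthesis errors
# ---------------------------------------------------------------------------


@dataclass
class ErrorModel:
    """Positional synthesis-error model for microarray oligos.

    Per-base rates are linearly interpolated from the 5' to the 3' end of
    the molecule; substitutions rise toward the 3' end (synthesized first),
    deletions toward the 5' end (synthesized last).
    """

    snp_rate_5prime: float = 0.001
    snp_rate_3prime: float = 0.005
    del_rate_5prime: float = 0.004
    del_rate_3prime: float = 0.001

    def __post_init__(self) -> None:
        for r in (
            self.snp_rate_5prime,
            self.snp_rate_3prime,
            self.del_rate_5prime,
            self.del_rate_3prime,
        ):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")

    def positional_rates(self, length: int) -> tuple[np.ndarray, np.ndarray]:
        x = np.linspace(0.0, 1.0, length)
        snp = self.snp_rate_5prime + (self.snp_rate_3prime - self.snp_rate_5prime) * x
        dele = self.del_rate_5prime + (self.del_rate_3prime - self.del_rate_5prime) * x
        return snp, dele

    def error_free_probability(self, length: int) -> float:
        snp, dele = self.positional_rates(length)
        return float(np.prod((1.0 - snp) * (1.0 - dele)))


def lognormal_abundance(n: int, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Skewed per-design abundance weights, normalized to sum 1."""
    w = rng.lognormal(mean=0.0, sigma=sigma, size=n)
    return w / w.sum()


def simulate_oligo_pool(
    designs: list[OligoDesign] | dict[str, str],
    n_molecules: int,
    error_model: ErrorModel | None = None,
    abundance_sigma: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw synthesized molecules from an oligo design.

    Returns a molecule table with columns ``molecule_id``, ``design_id``,
    ``sequence``, ``n_sub``, ``n_del``, ``sub_positions``, ``del_positions``,
    ``error_free``; positions refer to the design sequence, 5' end = 0.
    """
    error_model = error_model or ErrorModel()
    rng = np.random.default_rng(seed)
    if isinstance(designs, dict):
        ids, seqs = list(designs), list(designs.values())
    else:
        ids = [d.design_id for d in designs]
        seqs = [d.sequence for d in designs]
    weights = lognormal_abundance(len(ids), abundance_sigma, rng)
    draw = rng.choice(len(ids), size=n_molecules, p=weights)

    rows = []
    for di in range(len(ids)):
        members = np.flatnonzero(draw == di)
        m = len(members)
        if m == 0:
            continue
        seq = np.array(list(seqs[di]))
        L = len(seq)
        snp_p, del_p = error_model.positional_rates(L)
        subs = rng.random((m, L)) < snp_p
        dels = rng.random((m, L)) < del_p
        shift = rng.integers(1, 4, size=(m, L))
        base_idx = np.searchsorted(np.array(["A", "C", "G", "T"]), seq)
        mutated_idx = (base_idx[None, :] + shift) % 4
        bases = np.array(list("ACGT"))
        for j in range(m):
            sub_pos = np.flatnonzero(subs[j] & ~dels[j])
            del_pos = np.flatnonzero(dels[j])
            chars = seq.copy()
            chars[sub_pos] = bases[mutated_idx[j, sub_pos]]
            keep = np.ones(L, dtype=bool)
            keep[del_pos] = False
            rows.append(
                {
                    "molecule_id": int(members[j]),
                    "design_id": ids[di],
                    "sequence": "".join(chars[keep]),
                    "n_sub": int(len(sub_pos)),
                    "n_del": int(len(del_pos)),
                    "sub_positions": ",".join(map(str, sub_pos)),
                    "del_positions": ",".join(map(str, del_pos)),
                    "error_free": bool(len(sub_pos) == 0 and len(del_pos) == 0),
                }
            )
    out = pd.DataFrame(rows).sort_values("molecule_id").reset_index(drop=True)
    out["molecule_id"] = [f"mol{str(i).zfill(7)}" for i in range(len(out))]
    return out


# ---------------------------------------------------------------------------
# pooled clone libraries
# ---------------------------------------------------------------------------


@dataclass
class LibrarySpec:
    """Composition of a pooled tag library."""

    abundance_sigma: float = 1.0
    dark_clone_rate: float = 0.05
    off_target_rate: float = 0.002
    contaminant_rate: float = 0.016
    co_uptake_rate: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        for r in (
            self.dark_clone_rate,
            self.off_target_rate,
            self.contaminant_rate,
            self.co_uptake_rate,
        ):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")


def simulate_library(
    designs: list[OligoDesign],
    genome: AnnotatedGenome,
    spec: LibrarySpec | None = None,
    n_clones: int = 1000,
    foreign_designs: list[OligoDesign] | None = None,
) -> pd.DataFrame:
    """Draw a clone table for a pooled transformation.

    Columns: ``clone_id``, ``design_id``, ``clone_class`` (one of on_target,
    dark, off_target, contaminant, co_integrant), ``in_frame``,
    ``off_target_chrom``/``off_target_pos`` (off-target clones only),
    ``design_id_2`` (co-integrants only), ``abundance`` (relative cell
    count, log-normal).
    """
    spec = spec or LibrarySpec()
    rng = np.random.default_rng(spec.seed)
    foreign_designs = foreign_designs or []
    weights = lognormal_abundance(len(designs), spec.abundance_sigma, rng)

    u = rng.random(n_clones)
    draw = rng.choice(len(designs), size=n_clones, p=weights)
    draw2 = rng.choice(len(designs), size=n_clones, p=weights)
    abundances = rng.lognormal(0.0, spec.abundance_sigma, size=n_clones)
    co_u = rng.random(n_clones)
    rows = []
    chrom_names = list(genome.chromosomes)
    for i in range(n_clones):
        design = designs[int(draw[i])]
        row = {
            "clone_id": f"clone{i:06d}",
            "design_id": design.design_id,
            "orf_id": design.orf_id,
            "clone_class": "on_target",
            "in_frame": True,
            "off_target_chrom": "",
            "off_target_pos": -1,
            "design_id_2": "",
            "abundance": float(abundances[i]),
        }
        thr_off = spec.off_target_rate
        thr_cont = thr_off + spec.contaminant_rate
        thr_dark = thr_cont + spec.dark_clone_rate
        if u[i] < thr_off:
            chrom = str(rng.choice(chrom_names))
            pos = int(rng.integers(700, len(genome.chromosomes[chrom]) - 700))
            row.update(
                clone_class="off_target",
                in_frame=False,
                off_target_chrom=chrom,
                off_target_pos=pos,
            )
        elif u[i] < thr_cont and foreign_designs:
            fd = foreign_designs[int(rng.integers(len(foreign_designs)))]
            row.update(
                clone_class="contaminant",
                design_id=fd.design_id,
                orf_id=fd.orf_id,
                in_frame=True,
            )
        elif u[i] < thr_dark:
            row.update(clone_class="dark", in_frame=False)
        elif co_u[i] < spec.co_uptake_rate:
            row.update(
                clone_class="co_integrant", design_id_2=designs[int(draw2[i])].design_id
            )
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# junction-enrichment (Anchor-Seq style) paired reads
# ---------------------------------------------------------------------------


@dataclass
class AdapterSpec:
    """Declared layout of the paired junction reads.

    Mate 1 starts directly at the constant cassette region (``r1_anchor``
    must be its prefix).  Mate 2 is adapter-side:
    ``[barcode][UMI][r2_anchor][genomic sequence ...]``.
    """

    r1_anchor: str
    r2_anchor: str = "GACTGCGTACGT"
    barcode_len: int = 6
    umi_len: int = 8


def _apply_seq_errors(read: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0.0:
        return read
    arr = np.array(list(read))
    mask = rng.random(len(arr)) < rate
    if mask.any():
        idx = np.flatnonzero(mask)
        base_idx = np.searchsorted(np.array(["A", "C", "G", "T"]), arr[idx])
        arr[idx] = np.array(list("ACGT"))[(base_idx + rng.integers(1, 4, len(idx))) % 4]
    return "".join(arr)


def simulate_anchorseq_reads(
    clones: pd.DataFrame,
    references: dict[str, "object"],
    adapter: AdapterSpec,
    barcodes: dict[str, str],
    sample_of_clone: dict[str, str] | None = None,
    read_len: int = 150,
    insert_range: tuple[int, int] = (150, 400),
    mean_molecules_per_clone: float = 5.0,
    pcr_duplication: int = 5,
    seq_error_rate: float = 0.0,
    seed: int = 0,
    genome: AnnotatedGenome | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate paired junction reads for a clone table.

    ``references`` maps design_id -> :class:`~castling.quant.JunctionReference`
    (on-target and contaminant clones draw their fragments from it; off-target
    clones splice the SIC-derived reference head onto their ectopic locus).

    Returns ``(reads, truth)``: ``reads`` has columns ``pair_id``, ``sample``,
    ``read1``, ``read2``; ``truth`` has the UMI-level molecule counts per
    (sample, design) that a perfect quantification should recover —
    distinguishable molecules (distinct UMIs) whose template carries the
    cognate junction (off-target integrations are excluded: their genomic
    side does not extend the design's reference).
    """
    rng = np.random.default_rng(seed)
    sample_ids = list(barcodes)
    reads = []
    truth_umis: dict[tuple[str, str], set] = {}
    pair_id = 0
    for _, clone in clones.iterrows():
        sample = (
            sample_of_clone[clone.clone_id]
            if sample_of_clone is not None
            else sample_ids[0]
        )
        genotypes = [clone.design_id]
        if clone.clone_class == "co_integrant" and clone.design_id_2:
            genotypes.append(clone.design_id_2)
        n_mol = rng.poisson(mean_molecules_per_clone * clone.get("abundance", 1.0))
        for g in genotypes:
            ref = references.get(g)
            if ref is None:
                continue
            if clone.clone_class == "off_target" and genome is not None:
                head = ref.sequence[: ref.homology_len]
                chrom = genome.chromosomes[clone.off_target_chrom]
                tail = chrom[clone.off_target_pos : clone.off_target_pos + 600]
                template = head + tail
            else:
                template = ref.sequence
            for _ in range(max(n_mol, 0)):
                # UMIs are unique per (sample, genotype): an idealized UMI
                # space without birthday collisions, so the molecule table
                # stays exactly recoverable after deduplication
                used = truth_umis.setdefault((sample, g), set())
                while True:
                    umi = "".join(rng.choice(list("ACGT"), size=adapter.umi_len))
                    if umi not in used or clone.clone_class == "off_target":
                        break
                insert = int(rng.integers(insert_range[0], insert_range[1] + 1))
                insert = min(insert, len(template))
                fragment = template[:insert]
                r1 = fragment[:read_len]
                r2_payload = revcomp(fragment)[
                    : read_len - adapter.barcode_len - adapter.umi_len - len(adapter.r2_anchor)
                ]
                r2 = barcodes[sample] + umi + adapter.r2_anchor + r2_payload
                for _dup in range(pcr_duplication):
                    reads.append(
                        {
                            "pair_id": f"pair{pair_id:08d}",
                            "sample": sample,
                            "clone_id": clone.clone_id,
                            "design_id": g,
                            "umi": umi,
                            "read1": _apply_seq_errors(r1, seq_error_rate, rng),
                            "read2": _apply_seq_errors(r2, seq_error_rate, rng),
                        }
                    )
                    pair_id += 1
                if clone.clone_class != "off_target":
                    truth_umis.setdefault((sample, g), set()).add(umi)
    reads_df = pd.DataFrame(reads)
    truth = pd.DataFrame(
        [
            {"sample": s, "design_id": g, "molecules": len(umis)}
            for (s, g), umis in sorted(truth_umis.items())
            if umis
        ]
    )
    return reads_df, truth


def write_fastq_pair(reads: pd.DataFrame, path1, path2) -> None:
    """Write the simulated pairs as two 4-line Phred+33 FASTQ files."""
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for _, r in reads.iterrows():
            f1.write(f"@{r.pair_id}/1\n{r.read1}\n+\n{'I' * len(r.read1)}\n")
            f2.write(f"@{r.pair_id}/2\n{r.read2}\n+\n{'I' * len(r.read2)}\n")


# ---------------------------------------------------------------------------
# FACS binning
# ---------------------------------------------------------------------------

#: published bin fractions for the eight intensity gates (renormalized)
DEFAULT_BIN_FRACTIONS = (0.05, 0.20, 0.20, 0.20, 0.25, 0.05, 0.05, 0.01)


@dataclass
class BinSpec:
    """FACS sorting layout: bin fractions and measurement noise."""

    fractions: tuple[float, ...] = DEFAULT_BIN_FRACTIONS
    cells_per_genotype: int = 200
    noise_sd: float = 0.5
    reads_per_bin: int = 20_000
    seed: int = 0

    def __post_init__(self) -> None:
        if any(p <= 0 for p in self.fractions):
            raise ValueError("bin fractions must be positive")

    @property
    def p_b(self) -> np.ndarray:
        p = np.asarray(self.fractions, dtype=float)
        return p / p.sum()


def simulate_facs_bins(
    intensities: dict[str, float] | pd.Series,
    spec: BinSpec | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Sort cells of known log-intensity into bins and sequence each bin.

    Each genotype contributes ``cells_per_genotype`` cells whose measured
    intensity is the true value plus Gaussian noise; bin boundaries are the
    empirical quantiles of the pooled measured intensities at the cumulative
    bin fractions.  Read counts per bin are multinomial in the genotype cell
    counts of that bin.

    Returns ``(r, p_b)``: ``r`` is the genotype × bin UMI-count matrix,
    ``p_b`` the bin fractions as a Series indexed like ``r``'s columns.
    """
    spec = spec or BinSpec()
    rng = np.random.default_rng(spec.seed)
    intensities = pd.Series(intensities)
    G = len(intensities)
    n = spec.cells_per_genotype
    measured = (
        intensities.to_numpy()[:, None] + rng.normal(0.0, spec.noise_sd, size=(G, n))
    )
    flat = measured.ravel()
    p = spec.p_b
    edges = np.quantile(flat, np.cumsum(p)[:-1])
    bins = np.searchsorted(edges, measured)  # 0..len(p)-1 per cell

    names = [f"bin{i + 1}" for i in range(len(p))]
    counts = np.zeros((G, len(p)), dtype=int)
    for b in range(len(p)):
        cells = (bins == b).sum(axis=1)
        total = cells.sum()
        if total == 0:
            continue
        counts[:, b] = rng.multinomial(spec.reads_per_bin, cells / total)
    r = pd.DataFrame(counts, index=intensities.index, columns=names)
    return r, pd.Series(p, index=names)
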