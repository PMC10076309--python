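"""Assay definition and synthetic data generation.

The panel models a multiplex amplicon-sequencing assay for *Anopheles
stephensi* insecticide-resistance surveillance: ten ~500 bp amplicons across
six loci (four voltage-gated sodium channel domains, *ace1*, *rdl*, *GSTe2*,
plus *its2* and *cox1* for species identification/phylogenetics), each sample
tagged with an inline 6 bp barcode on both the forward and reverse primer.

Everything here is self-contained: reference sequences are synthetic (seeded
uniform base draws), gene models use toy coordinates, but ortholog codon
numbering (vgsc 958→1014 in *M. domestica*, rdl 296→301 in *D. melanogaster*)
and the resistance-marker catalogue match the published assay, so downstream
annotation and reporting exercise the real logic.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_LUT = np.zeros(256, dtype=np.int64)
for _i, _b in enumerate(b"ACGT"):
    _BASE_LUT[_b] = _i

#: Fixed seed for the default panel so every build is byte-identical.
_PANEL_SEED = 20221107

#: Phred offset for FASTQ output.
PHRED_OFFSET = 33


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def hamming(a: str, b: str) -> int:
    """Hamming distance between equal-length strings."""
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Amplicon:
    """One PCR amplicon of the panel.

    ``reference_seq`` starts with ``fwd_primer`` and ends with the reverse
    complement of ``rev_primer`` (primers are stored as synthesized, i.e. the
    reverse primer reads 5'→3' on the opposite strand).  ``genomic_offset``
    places the amplicon on its source contig (toy coordinates).
    """

    name: str
    reference_seq: str
    target_locus: str
    genomic_offset: int
    fwd_primer: str
    rev_primer: str

    def __post_init__(self) -> None:
        L = len(self.reference_seq)
        if not 150 <= L <= 1000:
            raise ValueError(f"{self.name}: reference length {L} outside [150, 1000]")
        if not self.reference_seq.startswith(self.fwd_primer):
            raise ValueError(f"{self.name}: reference does not start with fwd primer")
        if not self.reference_seq.endswith(revcomp(self.rev_primer)):
            raise ValueError(f"{self.name}: reference does not end with revcomp(rev primer)")

    @property
    def insert_start(self) -> int:
        return len(self.fwd_primer)

    @property
    def insert_end(self) -> int:
        return len(self.reference_seq) - len(self.rev_primer)

    def safe_name(self) -> str:
        """Name usable in file paths (``/`` → ``_``)."""
        return self.name.replace("/", "_")


@dataclass(frozen=True)
class GeneModel:
    """Coding model for the gene fragment covered by one amplicon.

    ``cds_intervals`` are 0-based half-open on the amplicon's source contig,
    ordered 5'→3' in genome (+) orientation.  ``codon_offset`` is the native
    codon number of the first complete codon of the modelled region (for minus
    strand genes the first codon sits at the rightmost interval end).
    ``ortholog_numbering`` maps species name → offset added to the native
    codon number to obtain the cross-species label.
    """

    gene: str
    strand: str
    cds_intervals: tuple[tuple[int, int], ...]
    codon_offset: int
    ortholog_numbering: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError("strand must be + or -")
        prev_end = -1
        for s, e in self.cds_intervals:
            if s >= e or s < prev_end:
                raise ValueError("CDS intervals must be ordered and non-overlapping")
            prev_end = e
        if self.cds_length % 3 != 0:
            raise ValueError("modelled CDS length must be a multiple of 3")

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds_intervals)

    def ortholog_label(self, native_codon: int, ref_aa: str, alt_aa: str) -> dict[str, str]:
        return {
            sp: f"{ref_aa}{native_codon + off}{alt_aa}"
            for sp, off in self.ortholog_numbering.items()
        }


@dataclass(frozen=True)
class ResistanceMarker:
    """A known (or candidate) resistance-associated amino-acid change."""

    gene: str
    native_codon: int
    ref_aa: str
    alt_aa: str
    ortholog_label: str
    known_association: str = ""

    def __post_init__(self) -> None:
        if self.ref_aa == self.alt_aa:
            raise ValueError("marker must change the amino acid")

    @property
    def native_label(self) -> str:
        return f"{self.ref_aa}{self.native_codon}{self.alt_aa}"


@dataclass
class AmpliconPanel:
    """The complete assay definition."""

    amplicons: list[Amplicon]
    gene_models: dict[str, GeneModel]          # keyed by amplicon name
    markers: list[ResistanceMarker]

    def __post_init__(self) -> None:
        names = [a.name for a in self.amplicons]
        if len(set(names)) != len(names):
            raise ValueError("amplicon names must be unique")
        seen = set()
        for m in self.markers:
            key = (m.gene, m.native_codon, m.alt_aa)
            if key in seen:
                raise ValueError(f"duplicate marker {key}")
            seen.add(key)

    def __iter__(self):
        return iter(self.amplicons)

    def __len__(self) -> int:
        return len(self.amplicons)

    def get(self, name: str) -> Amplicon:
        for a in self.amplicons:
            if a.name == name:
                return a
        raise KeyError(name)

    def marker(self, native_label: str) -> ResistanceMarker:
        for m in self.markers:
            if m.native_label == native_label:
                return m
        raise KeyError(native_label)


@dataclass
class SampleSheet:
    """sample ↔ (forward barcode, reverse barcode) ↔ pool mapping."""

    rows: list[tuple[str, str, str, str]]      # sample_id, fwd_bc, rev_bc, pool_id

    def __post_init__(self) -> None:
        per_pool: dict[str, set[tuple[str, str]]] = {}
        for sample, fwd, rev, pool in self.rows:
            if len(fwd) != 6 or len(rev) != 6:
                raise ValueError(f"{sample}: barcodes must be 6 bp")
            pairs = per_pool.setdefault(pool, set())
            if (fwd, rev) in pairs:
                raise ValueError(f"barcode pair collision in pool {pool}")
            pairs.add((fwd, rev))

    @property
    def samples(self) -> list[str]:
        return [r[0] for r in self.rows]

    @property
    def pools(self) -> list[str]:
        return sorted({r[3] for r in self.rows})

    def pool_of(self, sample_id: str) -> str:
        for s, _, _, p in self.rows:
            if s == sample_id:
                return p
        raise KeyError(sample_id)

    def barcodes(self, sample_id: str) -> tuple[str, str]:
        for s, f, r, _ in self.rows:
            if s == sample_id:
                return f, r
        raise KeyError(sample_id)

    def min_barcode_distance(self, pool: str | None = None) -> int:
        """Minimum pairwise Hamming distance among all barcodes of a pool."""
        bcs: set[str] = set()
        for _, f, r, p in self.rows:
            if pool is None or p == pool:
                bcs.update((f, r))
        bcs = sorted(bcs)
        if len(bcs) < 2:
            return 6
        return min(hamming(a, b) for i, a in enumerate(bcs) for b in bcs[i + 1:])

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.rows, columns=["sample_id", "fwd_barcode", "rev_barcode", "pool_id"])
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SampleSheet":
        df = pd.read_csv(path, sep="\t", dtype=str)
        return cls([tuple(r) for r in df[["sample_id", "fwd_barcode", "rev_barcode", "pool_id"]].itertuples(index=False)])


@dataclass
class PlantedVariant:
    """A variant planted by the simulator, VCF-style alleles.

    Substitutions have len(ref) == len(alt) == 1; insertions/deletions are
    single events of at most 10 inserted/deleted bases anchored on one
    reference base (e.g. ref ``A`` alt ``ATTG``; ref ``ACCT`` alt ``A``).
    """

    amplicon: str
    pos: int                     # 0-based on the amplicon reference
    ref: str
    alt: str
    freq: float                  # population allele frequency

    def __post_init__(self) -> None:
        if not 0.0 <= self.freq <= 1.0:
            raise ValueError("allele frequency must be in [0, 1]")
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")
        if abs(len(self.ref) - len(self.alt)) > 10:
            raise ValueError("indel events are limited to 10 bp")


@dataclass
class SimulationConfig:
    """Conditions for one simulated pool.

    Defaults mirror the assay's sequencing design: 2 × 250 bp paired-end
    reads, an average of 250 read pairs per amplicon-sample unit, and a small
    per-base substitution error rate with mostly high-quality bases.
    """

    n_samples: int
    amplicons: list[Amplicon]
    planted_variants: list[PlantedVariant] = field(default_factory=list)
    reads_per_amplicon_mean: float = 250.0
    read_length: int = 250
    base_error_rate: float = 0.001
    quality_model: tuple[int, int, float] = (37, 12, 0.02)   # high_q, low_q, fraction_low
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.base_error_rate <= 0.1:
            raise ValueError("base_error_rate must be in [0, 0.1]")
        by_name = {a.name: a for a in self.amplicons}
        for v in self.planted_variants:
            amp = by_name[v.amplicon]
            if self.read_length > len(amp.reference_seq):
                raise ValueError(f"read_length exceeds {amp.name} length")
            if v.pos < amp.insert_start or v.pos + len(v.ref) > amp.insert_end:
                raise ValueError(
                    f"planted site {v.amplicon}:{v.pos} falls inside primer/barcode region"
                )


# ---------------------------------------------------------------------------
# Default panel construction
# ---------------------------------------------------------------------------

# marker catalogue: gene, native codon, ref/alt aa, ref codon written into the
# synthetic reference, index of the substituted base within that codon, the
# substituting base, association note, and the amplicon carrying the codon.
_MARKER_DEFS = [
    ("vgsc", 958, "L", "F", "TTA", 2, "T", "kdr; pyrethroid/DDT target-site resistance", "VGSCII"),
    ("rdl", 296, "A", "S", "GCT", 0, "T", "dieldrin/cyclodiene resistance; fipronil cross-resistance", "Rdl1"),
    ("rdl", 327, "V", "I", "GTT", 0, "A", "secondary rdl substitution seen with A296S", "Rdl1"),
    ("rdl", 345, "T", "S", "ACT", 0, "T", "secondary rdl substitution seen with A296S", "Rdl2"),
    ("ace1", 119, "G", "S", "GGC", 0, "A", "carbamate/organophosphate target-site resistance", "ACE1_I"),
    ("ace1", 177, "N", "D", "AAT", 0, "G", "novel; not previously implicated in resistance", "ACE1_II"),
    ("gste2", 189, "V", "L", "GTG", 0, "T", "novel; not previously implicated in resistance", "GSTe2"),
]

_ORTHOLOG_NUMBERING = {
    "vgsc": {"M. domestica": 56},
    "rdl": {"D. melanogaster": 5},
}

# name, locus, amplicon length, strand, codon_offset (None → non-coding)
_AMPLICON_DEFS = [
    ("ACE1_I", "ace1", 500, "+", 89),
    ("ACE1_II", "ace1", 490, "+", 147),
    ("CO1", "cox1", 510, None, None),
    ("GSTe2", "gste2", 500, "-", 160),
    ("ITS2", "its2", 480, None, None),
    ("Rdl1", "rdl", 500, "+", 281),
    ("Rdl2", "rdl", 495, "+", 330),
    ("VGSCI", "vgsc", 505, "+", 820),
    ("VGSCII", "vgsc", 500, "+", 908),
    ("VGSCIII/IV", "vgsc", 520, "+", 1480),
]


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def build_default_panel() -> AmpliconPanel:
    """Build the ten-amplicon default panel with synthetic references.

    Amplicon names match the assay's coverage-table rows; coding amplicons
    carry gene models with the correct ortholog codon offsets, and the seven
    catalogued resistance markers have their reference codons written into the
    synthetic sequence so marker variants can be planted and re-discovered.
    """
    rng = np.random.default_rng(_PANEL_SEED)
    amplicons: list[Amplicon] = []
    gene_models: dict[str, GeneModel] = {}

    for idx, (name, locus, length, strand, codon_offset) in enumerate(_AMPLICON_DEFS):
        fwd = _random_dna(rng, int(rng.integers(20, 25)))
        rev = _random_dna(rng, int(rng.integers(20, 25)))
        seq = list(_random_dna(rng, length))
        seq[: len(fwd)] = fwd
        rc = revcomp(rev)
        seq[length - len(rev):] = rc
        genomic_offset = 1000 + 10 * idx

        insert_start = len(fwd)
        insert_end = length - len(rev)
        cds_len = ((insert_end - insert_start) // 3) * 3
        cds_amp = (insert_start, insert_start + cds_len)

        if strand is not None:
            # write marker reference codons into the sequence
            for gene, codon, ref_aa, alt_aa, ref_codon, sub_i, alt_b, assoc, amp_name in _MARKER_DEFS:
                if amp_name != name:
                    continue
                if strand == "+":
                    a0 = cds_amp[0] + (codon - codon_offset) * 3
                    seq[a0:a0 + 3] = ref_codon
                else:
                    a0 = cds_amp[1] - (codon - codon_offset + 1) * 3
                    seq[a0:a0 + 3] = revcomp(ref_codon)
                if not (cds_amp[0] <= a0 and a0 + 3 <= cds_amp[1]):
                    raise AssertionError("marker codon outside modelled CDS")
            gene_models[name] = GeneModel(
                gene=locus,
                strand=strand,
                cds_intervals=((genomic_offset + cds_amp[0], genomic_offset + cds_amp[1]),),
                codon_offset=codon_offset,
                ortholog_numbering=dict(_ORTHOLOG_NUMBERING.get(locus, {})),
            )

        amplicons.append(Amplicon(
            name=name,
            reference_seq="".join(seq),
            target_locus=locus,
            genomic_offset=genomic_offset,
            fwd_primer=fwd,
            rev_primer=rev,
        ))

    markers = []
    for gene, codon, ref_aa, alt_aa, _, _, _, assoc, amp_name in _MARKER_DEFS:
        off = _ORTHOLOG_NUMBERING.get(gene, {})
        if off:
            sp, o = next(iter(off.items()))
            label = f"{ref_aa}{codon + o}{alt_aa} ({sp})"
        else:
            label = f"{ref_aa}{codon}{alt_aa}"
        markers.append(ResistanceMarker(gene, codon, ref_aa, alt_aa, label, assoc))

    return AmpliconPanel(amplicons, gene_models, markers)


def marker_site(panel: AmpliconPanel, marker: ResistanceMarker) -> tuple[str, int, str, str]:
    """(amplicon, 0-based position, ref base, alt base) realising a marker.

    Returns the single-base substitution on the amplicon (+) strand whose
    codon change produces the marker's amino-acid change in the default panel.
    """
    for gene, codon, ref_aa, alt_aa, ref_codon, sub_i, alt_b, _, amp_name in _MARKER_DEFS:
        if (gene, codon, alt_aa) != (marker.gene, marker.native_codon, marker.alt_aa):
            continue
        amp = panel.get(amp_name)
        gm = panel.gene_models[amp_name]
        cds_s = gm.cds_intervals[0][0] - amp.genomic_offset
        cds_e = gm.cds_intervals[-1][1] - amp.genomic_offset
        if gm.strand == "+":
            a0 = cds_s + (codon - gm.codon_offset) * 3
            pos = a0 + sub_i
            return amp_name, pos, ref_codon[sub_i], alt_b
        a0 = cds_e - (codon - gm.codon_offset + 1) * 3
        pos = a0 + (2 - sub_i)
        comp = str.maketrans("ACGT", "TGCA")
        return amp_name, pos, ref_codon[sub_i].translate(comp), alt_b.translate(comp)
    raise KeyError(marker.native_label)


# ---------------------------------------------------------------------------
# Primer-dimer screen
# ---------------------------------------------------------------------------

def _three_prime_complement(primer_a: str, primer_b: str) -> int:
    """Longest 3'-terminal suffix of ``primer_a`` whose reverse complement is a
    substring of ``primer_b``."""
    best = 0
    for k in range(1, len(primer_a) + 1):
        if revcomp(primer_a[-k:]) in primer_b:
            best = k
        else:
            break
    return best


def screen_primer_dimers(panel: AmpliconPanel, max_3prime_complement: int = 5) -> pd.DataFrame:
    """Screen all unordered primer pairs for 3'-end complementarity.

    For every unordered pair (self-pairs included) the score is the longest
    perfect reverse-complement match involving either primer's 3' terminus;
    pairs whose score exceeds ``max_3prime_complement`` are flagged as
    potential dimerisation events.
    """
    primers: list[tuple[str, str]] = []
    for amp in panel:
        primers.append((f"{amp.name}_F", amp.fwd_primer))
        primers.append((f"{amp.name}_R", amp.rev_primer))
    rows = []
    for i in range(len(primers)):
        for j in range(i, len(primers)):
            (na, pa), (nb, pb) = primers[i], primers[j]
            score = max(_three_prime_complement(pa, pb), _three_prime_complement(pb, pa))
            rows.append((na, nb, score, score > max_3prime_complement))
    return pd.DataFrame(rows, columns=["primer_a", "primer_b", "three_prime_complement", "flagged"])


# ---------------------------------------------------------------------------
# Sample sheets
# ---------------------------------------------------------------------------

def _gf4_mul(x: int, y: int) -> int:
    """GF(4) product (polynomial basis, modulus x²+x+1)."""
    r = 0
    for i in range(2):
        if (y >> i) & 1:
            r ^= x << i
    if r & 4:
        r ^= 0b111
    return r & 3


def _rs_barcode_code() -> list[np.ndarray]:
    """Extended Reed–Solomon [6,3] code over GF(4): 64 words, distance 4."""
    code = []
    for a in range(4):
        for b in range(4):
            for c in range(4):
                w = [a ^ _gf4_mul(b, x) ^ _gf4_mul(c, _gf4_mul(x, x)) for x in range(4)]
                code.append(np.array(w + [c, b]))
    return code


def generate_barcodes(n: int, rng: np.random.Generator, min_distance: int = 3) -> list[str]:
    """Pick ``n`` 6-mer barcodes with pairwise Hamming distance ≥ min_distance.

    The first 64 barcodes come from an extended Reed–Solomon [6,3] code over
    GF(4) (pairwise distance 4, so 1-mismatch demultiplexing corrects every
    single substitution with margin), drawn in seeded random order.  Requests
    beyond 64 are filled greedily with random 6-mers at distance ≥
    ``min_distance`` from everything kept (a distance-3 6-mer code tops out
    near 90–100 words).
    """
    code = _rs_barcode_code()
    order = np.arange(len(code))
    rng.shuffle(order)
    kept_arr = [code[i] for i in order[:min(n, 64)]]
    if n > 64:
        kept_arr = [code[i] for i in order]
        candidates = np.arange(4 ** 6)
        rng.shuffle(candidates)
        for c in candidates:
            if len(kept_arr) >= n:
                break
            digits = np.array([(c >> (2 * k)) & 3 for k in range(6)])
            if all(int((digits != k).sum()) >= min_distance for k in kept_arr):
                kept_arr.append(digits)
        if len(kept_arr) < n:
            raise ValueError(f"cannot find {n} barcodes at distance {min_distance}")
        kept_arr = kept_arr[:n]
    return ["".join("ACGT"[d] for d in w) for w in kept_arr]


def make_sample_sheet(
    n_samples: int,
    n_pools: int = 1,
    seed: int = 0,
    prefix: str = "S",
) -> SampleSheet:
    """Generate a sample sheet with distance-≥3 barcodes within each pool.

    Samples are split round-robin across pools; each pool draws its own
    barcode code so large cohorts are not limited by the ~200-codeword
    capacity of a distance-3 6-mer code.
    """
    rng = np.random.default_rng(seed)
    pools: dict[str, list[str]] = {f"pool{p + 1}": [] for p in range(n_pools)}
    sample_ids = [f"{prefix}{i + 1:03d}" for i in range(n_samples)]
    for i, s in enumerate(sample_ids):
        pools[f"pool{(i % n_pools) + 1}"].append(s)
    rows: list[tuple[str, str, str, str]] = []
    for pool_id, members in pools.items():
        bcs = generate_barcodes(2 * len(members), rng)
        for k, s in enumerate(members):
            rows.append((s, bcs[2 * k], bcs[2 * k + 1], pool_id))
    rows.sort(key=lambda r: r[0])
    return SampleSheet(rows)


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulatedPool:
    """Simulator output: FASTQ paths plus truth tables."""

    r1_path: Path
    r2_path: Path
    genotype_truth: pd.DataFrame     # sample_id, amplicon, pos, ref, alt, genotype
    read_truth: pd.DataFrame         # read_id, sample_id, amplicon

    def write_truth_tsv(self, path: str | Path) -> None:
        self.genotype_truth.to_csv(path, sep="\t", index=False)


def _apply_variants(ref: str, variants: list[tuple[PlantedVariant, bool]]) -> str:
    """Apply alt alleles (descending position) to a template string."""
    seq = ref
    for v, carry in sorted(variants, key=lambda t: -t[0].pos):
        if carry:
            seq = seq[: v.pos] + v.alt + seq[v.pos + len(v.ref):]
    return seq


def _draw_genotype(rng: np.random.Generator, freq: float) -> str:
    """Hardy–Weinberg genotype draw at allele frequency ``freq``."""
    u = rng.random()
    if u < (1 - freq) ** 2:
        return "0/0"
    if u < (1 - freq) ** 2 + 2 * freq * (1 - freq):
        return "0/1"
    return "1/1"


def simulate_pool(
    cfg: SimulationConfig,
    sheet: SampleSheet,
    out_dir: str | Path,
    pool_id: str | None = None,
) -> SimulatedPool:
    """Simulate one pooled sequencing run to gzip FASTQ.

    Read 1 is ``fwd_barcode + amplicon 5' segment`` (the segment itself starts
    with the forward primer); read 2 is ``rev_barcode + reverse-complement
    segment`` (starting with the reverse primer).  Per-sample genotypes are
    drawn Hardy–Weinberg from each planted variant's population allele
    frequency; heterozygous fragments carry the alt allele with probability
    0.5 independently per fragment.  Base qualities follow the two-point
    quality model and substitution errors occur per base at
    ``base_error_rate`` for high-quality bases, scaled up by the phred ratio
    for low-quality bases.

    The number of amplicon-sample units must not exceed 200 (one pool's
    capacity); barcode collisions or planted sites inside primer regions are
    rejected at config construction.
    """
    rows = sheet.rows if pool_id is None else [r for r in sheet.rows if r[3] == pool_id]
    if not rows:
        raise ValueError("no samples selected for simulation")
    if len(rows) * len(cfg.amplicons) > 200:
        raise ValueError("pool capacity exceeded: at most 200 amplicon-sample units")
    pools_seen = {r[3] for r in rows}
    if len(pools_seen) > 1:
        raise ValueError("simulate one pool at a time (pass pool_id)")
    the_pool = next(iter(pools_seen))

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    high_q, low_q, frac_low = cfg.quality_model
    # low-quality bases err more, scaled by the phred ratio, capped at 0.75
    err_low = min(cfg.base_error_rate * 10 ** ((high_q - low_q) / 10), 0.75)

    variants_by_amp: dict[str, list[PlantedVariant]] = {}
    for v in cfg.planted_variants:
        variants_by_amp.setdefault(v.amplicon, []).append(v)

    geno_rows = []
    read_rows = []
    r1_path = out_dir / f"{the_pool}_R1.fastq.gz"
    r2_path = out_dir / f"{the_pool}_R2.fastq.gz"
    n_read = 0
    with gzip.open(r1_path, "wt") as f1, gzip.open(r2_path, "wt") as f2:
        for sample_id, fwd_bc, rev_bc, _ in rows:
            for amp in cfg.amplicons:
                planted = variants_by_amp.get(amp.name, [])
                genos = {id(v): _draw_genotype(rng, v.freq) for v in planted}
                for v in planted:
                    geno_rows.append((sample_id, amp.name, v.pos, v.ref, v.alt, genos[id(v)]))
                n_frags = int(rng.poisson(cfg.reads_per_amplicon_mean))
                for _ in range(n_frags):
                    carries = []
                    for v in planted:
                        g = genos[id(v)]
                        carry = g == "1/1" or (g == "0/1" and rng.random() < 0.5)
                        carries.append((v, carry))
                    template = _apply_variants(amp.reference_seq, carries)
                    seg = cfg.read_length - 6
                    s1 = fwd_bc + template[:seg]
                    s2 = rev_bc + revcomp(template)[:seg]
                    read_id = f"SIM:{the_pool}:{n_read:07d}"
                    n_read += 1
                    read_rows.append((read_id, sample_id, amp.name))
                    for s, fh in ((s1, f1), (s2, f2)):
                        arr = np.frombuffer(s.encode(), dtype=np.uint8).copy()
                        L = arr.size
                        lowmask = rng.random(L) < frac_low
                        quals = np.where(lowmask, low_q, high_q)
                        if cfg.base_error_rate > 0:
                            errp = np.where(lowmask, err_low, cfg.base_error_rate)
                            errs = rng.random(L) < errp
                            if errs.any():
                                idx = np.nonzero(errs)[0]
                                shift = rng.integers(1, 4, size=idx.size)
                                arr[idx] = _BASES[(_BASE_LUT[arr[idx]] + shift) % 4]
                        qual_str = "".join(chr(q + PHRED_OFFSET) for q in quals)
                        fh.write(f"@{read_id}\n{arr.tobytes().decode()}\n+\n{qual_str}\n")

    genotype_truth = pd.DataFrame(
        geno_rows, columns=["sample_id", "amplicon", "pos", "ref", "alt", "genotype"]
    )
    read_truth = pd.DataFrame(read_rows, columns=["read_id", "sample_id", "amplicon"])
    return SimulatedPool(r1_path, r2_path, genotype_truth, read_truth)


# ---------------------------------------------------------------------------
# Panel config round-trip
# ---------------------------------------------------------------------------

def write_panel(panel: AmpliconPanel, path: str | Path) -> None:
    """Serialise a panel to the sectioned key-value text format."""
    buf = io.StringIO()
    for amp in panel.amplicons:
        buf.write(f"[amplicon {amp.name}]\n")
        buf.write(f"target_locus = {amp.target_locus}\n")
        buf.write(f"genomic_offset = {amp.genomic_offset}\n")
        buf.write(f"fwd_primer = {amp.fwd_primer}\n")
        buf.write(f"rev_primer = {amp.rev_primer}\n")
        buf.write(f"reference_seq = {amp.reference_seq}\n\n")
    for amp_name in sorted(panel.gene_models):
        gm = panel.gene_models[amp_name]
        buf.write(f"[gene_model {amp_name}]\n")
        buf.write(f"gene = {gm.gene}\n")
        buf.write(f"strand = {gm.strand}\n")
        ivals = ";".join(f"{s}-{e}" for s, e in gm.cds_intervals)
        buf.write(f"cds_intervals = {ivals}\n")
        buf.write(f"codon_offset = {gm.codon_offset}\n")
        orth = ";".join(f"{sp}:{off}" for sp, off in sorted(gm.ortholog_numbering.items()))
        buf.write(f"ortholog_numbering = {orth}\n\n")
    for m in panel.markers:
        buf.write(f"[marker {m.gene}:{m.native_codon}]\n")
        buf.write(f"ref_aa = {m.ref_aa}\n")
        buf.write(f"alt_aa = {m.alt_aa}\n")
        buf.write(f"ortholog_label = {m.ortholog_label}\n")
        buf.write(f"known_association = {m.known_association}\n\n")
    Path(path).write_text(buf.getvalue())


def read_panel(path: str | Path) -> AmpliconPanel:
    """Parse a panel config written by :func:`write_panel`."""
    amplicons: list[Amplicon] = []
    gene_models: dict[str, GeneModel] = {}
    markers: list[ResistanceMarker] = []
    section: tuple[str, str] | None = None
    fields: dict[str, str] = {}

    def flush() -> None:
        if section is None:
            return
        kind, name = section
        if kind == "amplicon":
            amplicons.append(Amplicon(
                name=name,
                reference_seq=fields["reference_seq"],
                target_locus=fields["target_locus"],
                genomic_offset=int(fields["genomic_offset"]),
                fwd_primer=fields["fwd_primer"],
                rev_primer=fields["rev_primer"],
            ))
        elif kind == "gene_model":
            ivals = tuple(
                tuple(int(x) for x in part.split("-"))
                for part in fields["cds_intervals"].split(";")
            )
            orth = {}
            if fields.get("ortholog_numbering"):
                for part in fields["ortholog_numbering"].split(";"):
                    sp, off = part.rsplit(":", 1)
                    orth[sp] = int(off)
            gene_models[name] = GeneModel(
                gene=fields["gene"],
                strand=fields["strand"],
                cds_intervals=tuple((s, e) for s, e in ivals),
                codon_offset=int(fields["codon_offset"]),
                ortholog_numbering=orth,
            )
        elif kind == "marker":
            gene, codon = name.rsplit(":", 1)
            markers.append(ResistanceMarker(
                gene=gene,
                native_codon=int(codon),
                ref_aa=fields["ref_aa"],
                alt_aa=fields["alt_aa"],
                ortholog_label=fields["ortholog_label"],
                known_association=fields.get("known_association", ""),
            ))

    for line in Path(path).read_text().splitlines():
        line = line.rstrip()
        if not line:
            continue
        if line.startswith("["):
            flush()
            kind, name = line[1:-1].split(" ", 1)
            section = (kind, name)
            fields = {}
        else:
            k, _, v = line.partition(" = ")
            fields[k] = v
    flush()
    return AmpliconPanel(amplicons, gene_models, markers)
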