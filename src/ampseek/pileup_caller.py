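"""Amplicon-targeted alignment, pileups, dual-caller SNP/indel calling.

Demultiplexed reads are aligned to their amplicon reference (edit-distance
alignment in infix mode, with long non-reference end runs soft-clipped and
reads exceeding the maximum clip length discarded), overlapping mate bases
are reconciled, and per-position base/quality pileups feed two independent
callers:

* a frequency caller — emits a call wherever the most frequent non-reference
  allele reaches the minimum alternate-allele depth at sufficient depth, with
  a phred-scaled binomial-tail site quality against the sequencing error
  rate;
* a diploid genotype-likelihood caller — emits a call when the posterior of a
  non-reference genotype under a symmetric base-error model exceeds 0.99.

The union of both call sets is filtered with the assay's site rules (depth ≥
30, alternate depth ≥ 10, site quality ≥ 30 after base quality ≥ 30) and the
cross-sample replication rule (present in ≥ 2 samples spanning ≥ 2 pools);
genotypes are classified from the alternate-allele read fraction with the
25% / 75% rule (boundaries inclusive to the heterozygote).
"""

from __future__ import annotations

import gzip
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import edlib
import numpy as np
from scipy.stats import binom

from .panel_model import PHRED_OFFSET, Amplicon, AmpliconPanel, SampleSheet, revcomp
from .demux import ReadPair, _read_fastq_gz

_CIGAR_RE = re.compile(r"(\d+)([=XID])")

#: Anchor: a run of ≥ this many matches ends a soft-clippable end region.
_ANCHOR_RUN = 8

#: Reads with edit distance above this fraction of their length are discarded.
_MAX_EDIT_FRACTION = 0.25

_MAX_PHRED = 1000.0


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class FilterConfig:
    """Site and cross-sample filter thresholds (assay defaults)."""

    min_base_qual: int = 30
    min_depth: int = 30
    min_alt_depth: int = 10
    min_site_qual: float = 30.0
    min_samples: int = 2
    min_pools: int = 2
    het_low: float = 0.25
    het_high: float = 0.75
    max_clip: int = 50

    def __post_init__(self) -> None:
        if not 0.0 <= self.het_low < self.het_high <= 1.0:
            raise ValueError("het band must satisfy 0 <= low < high <= 1")
        if self.min_depth <= 0 or self.min_alt_depth <= 0:
            raise ValueError("depth thresholds must be positive")


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------

@dataclass
class Alignment:
    """Per-base reference placement of one read.

    ``bases`` maps 0-based reference position → (base, phred);
    ``deletions`` are (ref_start, length) events; ``insertions`` are
    (ref_pos_after, inserted_seq) events with a representative phred.
    """

    bases: dict[int, tuple[str, int]]
    deletions: list[tuple[int, int]]
    insertions: list[tuple[int, str, int]]
    clipped: int
    edit_distance: int


def _parse_cigar(cigar: str) -> list[tuple[int, str]]:
    return [(int(n), op) for n, op in _CIGAR_RE.findall(cigar)]


def _soft_clip_bounds(ops: list[tuple[int, str]]) -> tuple[int, int, int, int]:
    """Query/op indices delimiting the anchored core of the alignment.

    Leading and trailing regions before/after the first/last ``=`` run of at
    least ``_ANCHOR_RUN`` are treated as soft clips (their query bases do not
    enter the pileup).  Returns (first_op, last_op_exclusive, lead_clip_query,
    tail_clip_query).
    """
    first = 0
    lead_q = 0
    for i, (n, op) in enumerate(ops):
        if op == "=" and n >= _ANCHOR_RUN:
            first = i
            break
        if op in "=XI":
            lead_q += n
    else:
        return 0, 0, sum(n for n, op in ops if op in "=XI"), 0
    last = len(ops)
    tail_q = 0
    for i in range(len(ops) - 1, -1, -1):
        n, op = ops[i]
        if op == "=" and n >= _ANCHOR_RUN:
            last = i + 1
            break
        if op in "=XI":
            tail_q += n
    return first, last, lead_q, tail_q


def align_to_amplicon(
    seq: str,
    quals: Sequence[int],
    amplicon: Amplicon,
    max_clip: int = 50,
    orientation: str = "fwd",
) -> Alignment | None:
    """Align one read to its amplicon reference; None when discarded.

    ``orientation="rev"`` reverse-complements the read first (read 2 is
    sequenced from the opposite strand).  Alignment is edit-distance infix
    alignment; end regions that fail to anchor on the reference are soft
    clipped, and reads whose total clipped length exceeds ``max_clip`` or
    whose edit distance exceeds a fixed fraction of their length are
    discarded.
    """
    if orientation == "rev":
        seq = revcomp(seq)
        quals = list(quals)[::-1]
    if not seq:
        return None
    res = edlib.align(seq, amplicon.reference_seq, mode="HW", task="path")
    if res["editDistance"] < 0 or res["editDistance"] > _MAX_EDIT_FRACTION * len(seq):
        return None
    ops = _parse_cigar(res["cigar"])
    tstart = res["locations"][0][0]
    first, last, lead_clip, tail_clip = _soft_clip_bounds(ops)
    if lead_clip + tail_clip > max_clip:
        return None

    bases: dict[int, tuple[str, int]] = {}
    deletions: list[tuple[int, int]] = []
    insertions: list[tuple[int, str, int]] = []
    q = 0
    t = tstart
    for i, (n, op) in enumerate(ops):
        in_core = first <= i < last
        if op == "=" or op == "X":
            if in_core:
                for k in range(n):
                    bases[t + k] = (seq[q + k], quals[q + k])
            q += n
            t += n
        elif op == "I":
            if in_core:
                ins_q = min(quals[q: q + n]) if n else 0
                insertions.append((t, seq[q: q + n], ins_q))
            q += n
        elif op == "D":
            if in_core:
                deletions.append((t, n))
            t += n
    return Alignment(bases, deletions, insertions, lead_clip + tail_clip, res["editDistance"])


def reconcile_mates(a1: Alignment | None, a2: Alignment | None) -> Alignment | None:
    """Merge mate alignments into one fragment observation.

    Positions covered by both mates contribute a single observation: agreeing
    bases keep the higher phred; disagreeing bases keep the higher-phred base
    with its quality capped at the phred difference.  Indel events present in
    either mate are kept once.
    """
    if a1 is None:
        return a2
    if a2 is None:
        return a1
    bases = dict(a1.bases)
    for pos, (b2, q2) in a2.bases.items():
        if pos not in bases:
            bases[pos] = (b2, q2)
            continue
        b1, q1 = bases[pos]
        if b1 == b2:
            bases[pos] = (b1, max(q1, q2))
        elif q2 > q1:
            bases[pos] = (b2, q2 - q1)
        else:
            bases[pos] = (b1, q1 - q2)
    dels = sorted(set(a1.deletions) | set(a2.deletions))
    ins_keys = {}
    for pos, s, q in a1.insertions + a2.insertions:
        if (pos, s) not in ins_keys or q > ins_keys[(pos, s)]:
            ins_keys[(pos, s)] = q
    ins = sorted((p, s, q) for (p, s), q in ins_keys.items())
    return Alignment(bases, dels, ins, a1.clipped + a2.clipped,
                     a1.edit_distance + a2.edit_distance)


# ---------------------------------------------------------------------------
# Pileup
# ---------------------------------------------------------------------------

_BASE_IDX = {"A": 0, "C": 1, "G": 2, "T": 3}
_DEL_IDX = 4


@dataclass
class PileupMatrix:
    """Per-position base/quality counts for one (sample, amplicon)."""

    amplicon: str
    sample_id: str
    ref: str
    counts: np.ndarray                        # (L, 5): A C G T deletion
    obs: list[list[tuple[str, int]]]          # per-position (base, phred), quality-passing
    insertions: dict[tuple[int, str], int]    # (pos_after, seq) → fragment count
    n_fragments: int = 0
    n_discarded: int = 0

    def depth(self, pos: int) -> int:
        return int(self.counts[pos].sum())

    def mean_depth(self) -> float:
        return float(self.counts.sum(axis=1).mean())


def build_pileup(
    fragments: Iterable[Alignment],
    amplicon: Amplicon,
    sample_id: str,
    min_base_qual: int = 30,
) -> PileupMatrix:
    """Accumulate reconciled fragment alignments into a pileup.

    Base observations below ``min_base_qual`` are excluded from both counts
    and the observation lists; deletion observations inherit the minimum
    flanking base quality of their fragment.
    """
    L = len(amplicon.reference_seq)
    counts = np.zeros((L, 5), dtype=np.int64)
    obs: list[list[tuple[str, int]]] = [[] for _ in range(L)]
    insertions: dict[tuple[int, str], int] = {}
    n_frag = 0
    for frag in fragments:
        if frag is None:
            continue
        n_frag += 1
        for pos, (b, q) in frag.bases.items():
            if q >= min_base_qual and b in _BASE_IDX and pos < L:
                counts[pos, _BASE_IDX[b]] += 1
                obs[pos].append((b, q))
        for start, dlen in frag.deletions:
            flank_q = min(
                frag.bases.get(start - 1, ("N", 0))[1],
                frag.bases.get(start + dlen, ("N", 0))[1],
            )
            if flank_q >= min_base_qual:
                for k in range(dlen):
                    if start + k < L:
                        counts[start + k, _DEL_IDX] += 1
                        obs[start + k].append(("-", flank_q))
        for pos, s, q in frag.insertions:
            if q >= min_base_qual:
                insertions[(pos, s)] = insertions.get((pos, s), 0) + 1
    return PileupMatrix(
        amplicon.name, sample_id, amplicon.reference_seq, counts, obs, insertions,
        n_fragments=n_frag,
    )


def pileup_from_fastq(
    r1: str | Path,
    r2: str | Path,
    amplicon: Amplicon,
    sample_id: str,
    cfg: FilterConfig | None = None,
) -> PileupMatrix:
    """Align a demultiplexed FASTQ pair and build its pileup."""
    cfg = cfg or FilterConfig()
    frags = []
    it2 = _read_fastq_gz(r2)
    for (id1, s1, q1), (id2, s2, q2) in zip(_read_fastq_gz(r1), it2):
        if id1 != id2:
            raise ValueError("demux bin mates desynchronised")
        a1 = align_to_amplicon(s1, q1, amplicon, cfg.max_clip, "fwd")
        a2 = align_to_amplicon(s2, q2, amplicon, cfg.max_clip, "rev")
        frags.append(reconcile_mates(a1, a2))
    p = build_pileup([f for f in frags if f is not None], amplicon, sample_id,
                     cfg.min_base_qual)
    p.n_discarded = sum(f is None for f in frags)
    return p


# ---------------------------------------------------------------------------
# Calls
# ---------------------------------------------------------------------------

@dataclass
class VariantCall:
    amplicon: str
    pos: int                     # 0-based on the amplicon reference
    ref: str
    alt: str
    dp: int
    ad_ref: int
    ad_alt: int
    site_qual: float
    caller_set: frozenset[str] = frozenset()
    filter_flags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError("alt must differ from ref")
        if self.ad_ref + self.ad_alt > self.dp:
            raise ValueError("allele depths exceed total depth")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.amplicon, self.pos, self.ref, self.alt)

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != len(self.alt)


@dataclass
class GenotypeCall:
    call: VariantCall
    genotype: str                # hom_ref | het | hom_alt
    alt_fraction: float


def _mean_error_prob(observations: list[tuple[str, int]]) -> float:
    if not observations:
        return 1e-3
    return float(np.mean([10 ** (-q / 10) for _, q in observations]))


def _site_qual_binomial(dp: int, ad_alt: int, err: float) -> float:
    """Phred-scaled binomial tail: P(≥ ad_alt error bases | dp, err)."""
    # a specific alternate base arises from 1/3 of substitution errors
    p = binom.sf(ad_alt - 1, dp, min(err / 3, 0.999))
    if p <= 0:
        return _MAX_PHRED
    return min(-10.0 * math.log10(p), _MAX_PHRED)


def _apply_site_flags(call: VariantCall, cfg: FilterConfig) -> VariantCall:
    if call.dp < cfg.min_depth:
        call.filter_flags.add("min_dp")
    if call.ad_alt < cfg.min_alt_depth:
        call.filter_flags.add("min_ad")
    if call.site_qual < cfg.min_site_qual:
        call.filter_flags.add("min_qual")
    return call


def call_variants_freq(p: PileupMatrix, cfg: FilterConfig | None = None) -> list[VariantCall]:
    """Frequency caller: top non-reference allele per site (SNPs + indels)."""
    cfg = cfg or FilterConfig()
    calls: list[VariantCall] = []
    L = len(p.ref)
    dels = _collect_deletion_events(p)
    for pos in range(L):
        dp = p.depth(pos)
        if dp < cfg.min_depth:
            continue
        ref_b = p.ref[pos]
        ref_i = _BASE_IDX.get(ref_b)
        row = p.counts[pos]
        cand = [(int(row[i]), b) for b, i in _BASE_IDX.items() if b != ref_b]
        cand.sort(key=lambda t: (-t[0], t[1]))
        if not cand or cand[0][0] < cfg.min_alt_depth:
            continue
        ad_alt, alt_b = cand[0]
        ad_ref = int(row[ref_i]) if ref_i is not None else 0
        err = _mean_error_prob(p.obs[pos])
        call = VariantCall(
            p.amplicon, pos, ref_b, alt_b, dp, ad_ref, ad_alt,
            _site_qual_binomial(dp, ad_alt, err),
            caller_set=frozenset({"freq"}),
        )
        calls.append(_apply_site_flags(call, cfg))
    # indels: single-event alleles, VCF-style anchored on the previous base
    for (start, dlen), count in dels.items():
        if start == 0:
            continue
        anchor = start - 1
        dp = p.depth(anchor)
        if dp < cfg.min_depth or count < cfg.min_alt_depth:
            continue
        ref_allele = p.ref[anchor: start + dlen]
        alt_allele = p.ref[anchor]
        ad_ref = max(dp - count, 0)
        err = _mean_error_prob(p.obs[anchor])
        call = VariantCall(
            p.amplicon, anchor, ref_allele, alt_allele, dp, ad_ref, count,
            _site_qual_binomial(dp, count, err),
            caller_set=frozenset({"freq"}),
        )
        calls.append(_apply_site_flags(call, cfg))
    for (pos, seq), count in sorted(p.insertions.items()):
        if pos == 0:
            continue
        anchor = pos - 1
        dp = p.depth(anchor)
        if dp < cfg.min_depth or count < cfg.min_alt_depth:
            continue
        ref_allele = p.ref[anchor]
        alt_allele = p.ref[anchor] + seq
        ad_ref = max(dp - count, 0)
        err = _mean_error_prob(p.obs[anchor])
        call = VariantCall(
            p.amplicon, anchor, ref_allele, alt_allele, dp, ad_ref, count,
            _site_qual_binomial(dp, count, err),
            caller_set=frozenset({"freq"}),
        )
        calls.append(_apply_site_flags(call, cfg))
    calls.sort(key=lambda c: (c.pos, c.ref, c.alt))
    return calls


def _collect_deletion_events(p: PileupMatrix) -> dict[tuple[int, int], int]:
    """Reconstruct single deletion events from per-position deletion counts.

    The pileup stores deletion support per position; contiguous runs with
    equal support are merged back into single events (the simulator plants
    single-event indels, so runs are unambiguous at calling depth).
    """
    events: dict[tuple[int, int], int] = {}
    L = len(p.ref)
    pos = 0
    while pos < L:
        c = int(p.counts[pos, _DEL_IDX])
        if c == 0:
            pos += 1
            continue
        end = pos
        while end + 1 < L and int(p.counts[end + 1, _DEL_IDX]) == c:
            end += 1
        events[(pos, end - pos + 1)] = c
        pos = end + 1
    return events


def _genotype_likelihoods(
    observations: list[tuple[str, int]], ref: str, alt: str
) -> tuple[float, float, float]:
    """Log10 likelihoods of (hom_ref, het, hom_alt) under symmetric errors."""
    ll = [0.0, 0.0, 0.0]
    for b, q in observations:
        e = 10 ** (-q / 10)
        for gi, f_alt in enumerate((0.0, 0.5, 1.0)):
            if b == alt:
                pr = f_alt * (1 - e) + (1 - f_alt) * (e / 3)
            elif b == ref:
                pr = (1 - f_alt) * (1 - e) + f_alt * (e / 3)
            else:
                pr = e / 3
            ll[gi] += math.log10(max(pr, 1e-300))
    return tuple(ll)


def call_variants_bayes(
    p: PileupMatrix,
    cfg: FilterConfig | None = None,
    posterior_threshold: float = 0.99,
) -> list[VariantCall]:
    """Diploid genotype-likelihood caller (SNPs only).

    Emits a call where the posterior probability of a non-reference genotype
    (uniform prior over hom_ref/het/hom_alt) exceeds ``posterior_threshold``;
    the site quality is the phred of P(hom_ref | data).
    """
    cfg = cfg or FilterConfig()
    calls: list[VariantCall] = []
    for pos in range(len(p.ref)):
        ref_b = p.ref[pos]
        ref_i = _BASE_IDX.get(ref_b)
        if ref_i is None:
            continue
        row = p.counts[pos]
        cand = [(int(row[i]), b) for b, i in _BASE_IDX.items() if b != ref_b]
        cand.sort(key=lambda t: (-t[0], t[1]))
        if not cand or cand[0][0] == 0:
            continue
        ad_alt, alt_b = cand[0]
        ll = _genotype_likelihoods(p.obs[pos], ref_b, alt_b)
        m = max(ll)
        probs = [10 ** (l - m) for l in ll]
        tot = sum(probs)
        post = [pr / tot for pr in probs]
        if post[1] + post[2] <= posterior_threshold:
            continue
        site_qual = min(-10.0 * math.log10(max(post[0], 1e-100)), _MAX_PHRED)
        call = VariantCall(
            p.amplicon, pos, ref_b, alt_b, p.depth(pos), int(row[ref_i]), ad_alt,
            site_qual, caller_set=frozenset({"bayes"}),
        )
        calls.append(_apply_site_flags(call, cfg))
    return calls


def merge_callers(
    freq_calls: list[VariantCall], bayes_calls: list[VariantCall]
) -> list[VariantCall]:
    """Union of both callers' sites with provenance.

    Sites found by a single caller are flagged ``single_caller``; conflicting
    alt alleles at one position are kept as independent records (each
    flagged).  Allele depths come from the shared pileup, so records for the
    same key are identical and the freq record is kept.
    """
    merged: dict[tuple, VariantCall] = {}
    for c in freq_calls + bayes_calls:
        if c.key in merged:
            prev = merged[c.key]
            prev.caller_set = prev.caller_set | c.caller_set
            prev.site_qual = max(prev.site_qual, c.site_qual)
            prev.filter_flags &= c.filter_flags
        else:
            merged[c.key] = VariantCall(
                c.amplicon, c.pos, c.ref, c.alt, c.dp, c.ad_ref, c.ad_alt,
                c.site_qual, c.caller_set, set(c.filter_flags),
            )
    out = []
    positions: dict[int, int] = {}
    for c in merged.values():
        positions[c.pos] = positions.get(c.pos, 0) + 1
    for c in merged.values():
        if len(c.caller_set) == 1:
            c.filter_flags.add("single_caller")
        if positions[c.pos] > 1:
            c.filter_flags.add("shared_position")
        out.append(c)
    out.sort(key=lambda c: (c.pos, c.ref, c.alt))
    return out


def classify_genotype(v: VariantCall, cfg: FilterConfig | None = None) -> GenotypeCall | None:
    """25/75 rule on the alternate-allele read fraction.

    < 25% alternate reads → hom_ref, > 75% → hom_alt, 25–75% (inclusive) →
    het.  Zero allele depth → no call (None).
    """
    cfg = cfg or FilterConfig()
    denom = v.ad_ref + v.ad_alt
    if denom == 0:
        return None
    f = v.ad_alt / denom
    if f < cfg.het_low:
        g = "hom_ref"
    elif f > cfg.het_high:
        g = "hom_alt"
    else:
        g = "het"
    return GenotypeCall(v, g, f)


def cross_sample_filter(
    calls: dict[str, list[GenotypeCall]],
    sheet: SampleSheet,
    cfg: FilterConfig | None = None,
) -> set[tuple[str, int, str, str]]:
    """Replication filter: keep variant keys carried (non-hom-ref, site
    filters passing) by ≥ min_samples samples spanning ≥ min_pools pools.

    Per-sample records of dropped keys are flagged (``singleton`` /
    ``single_pool``), never deleted.  Samples missing from the sheet are a
    hard error.
    """
    cfg = cfg or FilterConfig()
    known = set(sheet.samples)
    carriers: dict[tuple, set[str]] = {}
    for sample_id, gcalls in calls.items():
        if sample_id not in known:
            raise KeyError(f"sample {sample_id} missing from sample sheet")
        for gc in gcalls:
            if gc.genotype == "hom_ref":
                continue
            if gc.call.filter_flags & {"min_dp", "min_ad", "min_qual"}:
                continue
            carriers.setdefault(gc.call.key, set()).add(sample_id)
    retained: set[tuple] = set()
    for key, samples in carriers.items():
        pools = {sheet.pool_of(s) for s in samples}
        if len(samples) >= cfg.min_samples and len(pools) >= cfg.min_pools:
            retained.add(key)
    for gcalls in calls.values():
        for gc in gcalls:
            key = gc.call.key
            samples = carriers.get(key, set())
            if len(samples) < cfg.min_samples:
                gc.call.filter_flags.add("singleton")
            elif len({sheet.pool_of(s) for s in samples}) < cfg.min_pools:
                gc.call.filter_flags.add("single_pool")
    return retained


# ---------------------------------------------------------------------------
# Orchestration over a demultiplexed pool + VCF output
# ---------------------------------------------------------------------------

def call_sample_amplicon(
    demux_dir: str | Path,
    sample_id: str,
    amplicon: Amplicon,
    cfg: FilterConfig | None = None,
) -> tuple[PileupMatrix, list[GenotypeCall]] | None:
    """Pileup + merged dual-caller genotypes for one demux bin; None if the
    bin has no reads."""
    cfg = cfg or FilterConfig()
    stem = Path(demux_dir) / f"{sample_id}.{amplicon.safe_name()}"
    r1 = Path(f"{stem}.R1.fastq.gz")
    if not r1.exists():
        return None
    p = pileup_from_fastq(r1, Path(f"{stem}.R2.fastq.gz"), amplicon, sample_id, cfg)
    merged = merge_callers(call_variants_freq(p, cfg), call_variants_bayes(p, cfg))
    gcalls = [g for g in (classify_genotype(v, cfg) for v in merged) if g is not None]
    return p, gcalls


def call_pool(
    demux_dir: str | Path,
    panel: AmpliconPanel,
    sheet: SampleSheet,
    cfg: FilterConfig | None = None,
) -> tuple[dict[str, list[GenotypeCall]], dict[tuple[str, str], PileupMatrix], set]:
    """Run both callers over every demux bin and apply the replication filter.

    Returns (per-sample genotype calls, pileups keyed by (sample, amplicon),
    retained variant keys).
    """
    cfg = cfg or FilterConfig()
    calls: dict[str, list[GenotypeCall]] = {}
    pileups: dict[tuple[str, str], PileupMatrix] = {}
    for sample_id in sheet.samples:
        sample_calls: list[GenotypeCall] = []
        for amp in panel:
            out = call_sample_amplicon(demux_dir, sample_id, amp, cfg)
            if out is None:
                continue
            p, gcalls = out
            pileups[(sample_id, amp.name)] = p
            sample_calls.extend(gcalls)
        calls[sample_id] = sample_calls
    retained = cross_sample_filter(calls, sheet, cfg)
    return calls, pileups, retained


def write_vcf(
    path: str | Path,
    panel: AmpliconPanel,
    calls: dict[str, list[GenotypeCall]],
    retained: set,
    deterministic: bool = True,
) -> None:
    """Write merged per-sample genotypes as VCF 4.2 (1-based positions).

    FILTER carries ``min_dp``/``min_ad``/``min_qual``/``singleton``/
    ``single_pool`` flags; INFO carries the caller set and per-sample
    alternate-allele fractions.
    """
    samples = sorted(calls)
    by_key: dict[tuple, dict[str, GenotypeCall]] = {}
    for s, gcalls in calls.items():
        for gc in gcalls:
            by_key.setdefault(gc.call.key, {})[s] = gc
    gt_code = {"hom_ref": "0/0", "het": "0/1", "hom_alt": "1/1"}
    lines = [
        "##fileformat=VCFv4.2",
        '##FILTER=<ID=min_dp,Description="Depth below minimum">',
        '##FILTER=<ID=min_ad,Description="Alternate allele depth below minimum">',
        '##FILTER=<ID=min_qual,Description="Site quality below minimum">',
        '##FILTER=<ID=singleton,Description="Present in fewer samples than required">',
        '##FILTER=<ID=single_pool,Description="Carriers span fewer pools than required">',
        '##FILTER=<ID=single_caller,Description="Emitted by one caller only">',
        '##FILTER=<ID=shared_position,Description="Multi-allelic position">',
        '##INFO=<ID=CS,Number=.,Type=String,Description="Caller set">',
        '##INFO=<ID=AFRAC,Number=.,Type=String,Description="Per-sample alternate allele fractions">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">',
    ]
    for amp in panel:
        lines.append(f"##contig=<ID={amp.safe_name()},length={len(amp.reference_seq)}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples))
    for key in sorted(by_key, key=lambda k: (k[0], k[1], k[2], k[3])):
        amp_name, pos, ref, alt = key
        per_sample = by_key[key]
        flags = set()
        callers = set()
        best_q = 0.0
        for gc in per_sample.values():
            flags |= gc.call.filter_flags
            callers |= gc.call.caller_set
            best_q = max(best_q, gc.call.site_qual)
        if key in retained:
            filt = "PASS"
        else:
            sitef = flags & {"singleton", "single_pool", "min_dp", "min_ad", "min_qual"}
            filt = ";".join(sorted(sitef)) or "singleton"
        afrac = ",".join(
            f"{s}:{per_sample[s].alt_fraction:.6g}" for s in samples if s in per_sample
        )
        info = f"CS={'|'.join(sorted(callers))};AFRAC={afrac}"
        cols = [
            panel.get(amp_name).safe_name(), str(pos + 1), ".", ref, alt,
            f"{best_q:.6g}", filt, info, "GT:AD:DP",
        ]
        for s in samples:
            gc = per_sample.get(s)
            if gc is None:
                cols.append("./.:.:.")
            else:
                cols.append(
                    f"{gt_code[gc.genotype]}:{gc.call.ad_ref},{gc.call.ad_alt}:{gc.call.dp}"
                )
        lines.append("\t".join(cols))
    Path(path).write_text("\n".join(lines) + "\n")
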