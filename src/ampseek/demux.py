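"""Inline-barcode demultiplexing and per-amplicon coverage accounting.

Each mate of a read pair begins with a 6 bp sample barcode followed by the
locus primer.  A pair is assigned to a sample only when the forward-read and
reverse-read barcodes resolve to the *same* sample (the barcode combination),
and to an amplicon by its read-1 primer, cross-checked against the read-2
primer when that maps.  Technical bases (barcode + primer) are trimmed from
assigned reads; 3' ends are quality-trimmed first.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .panel_model import PHRED_OFFSET, AmpliconPanel, SampleSheet, hamming

UNASSIGNED = "UNASSIGNED"

BARCODE_LEN = 6


@dataclass
class ReadPair:
    id: str
    seq1: str
    seq2: str
    qual1: list[int]
    qual2: list[int]

    def __post_init__(self) -> None:
        if len(self.seq1) != len(self.qual1) or len(self.seq2) != len(self.qual2):
            raise ValueError("sequence/quality length mismatch")


@dataclass
class DemuxResult:
    read_id: str
    sample_id: str                  # or UNASSIGNED
    amplicon: str                   # or UNASSIGNED
    barcode_mismatches: int
    primer_mismatches: int
    pair: ReadPair                  # trimmed when assigned, untouched otherwise
    reason: str = ""


@dataclass
class CoverageReport:
    """Read-pair accounting for one demultiplexed pool."""

    pair_counts: pd.DataFrame       # index sample_id, columns amplicon names
    total: int
    assigned: int
    unassigned: int
    unassigned_reasons: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.assigned + self.unassigned != self.total:
            raise ValueError("count conservation violated")

    def mean_coverage(self) -> pd.Series:
        """Mean assigned pairs per amplicon across samples."""
        return self.pair_counts.mean(axis=0)

    def to_tsv(self, path: str | Path) -> None:
        """Coverage-table layout: amplicon rows, mean-coverage column."""
        mean = self.mean_coverage()
        df = pd.DataFrame({
            "amplicon": mean.index,
            "mean_coverage": [f"{v:.2f}" for v in mean.values],
            "total_pairs": self.pair_counts.sum(axis=0).reindex(mean.index).astype(int).values,
        })
        df.to_csv(path, sep="\t", index=False)


def match_barcode(
    prefix: str,
    sheet: SampleSheet,
    max_mismatch: int = 1,
    side: str = "fwd",
) -> list[tuple[str, int]]:
    """Samples whose ``side`` barcode lies within ``max_mismatch`` of prefix.

    Returns ``(sample_id, distance)`` pairs at the minimum observed distance
    only; two or more candidates at equal distance signal ambiguity and the
    caller must treat the read as unassigned.
    """
    if len(prefix) != BARCODE_LEN:
        raise ValueError("barcode prefix must be 6 bp")
    col = 1 if side == "fwd" else 2
    best = max_mismatch + 1
    out: list[tuple[str, int]] = []
    for row in sheet.rows:
        d = hamming(prefix, row[col])
        if d < best:
            best = d
            out = [(row[0], d)]
        elif d == best and d <= max_mismatch:
            out.append((row[0], d))
    return out if best <= max_mismatch else []


def assign_amplicon(
    trimmed_prefix: str,
    panel: AmpliconPanel,
    max_primer_mismatch: int = 2,
    side: str = "fwd",
) -> tuple[str, int]:
    """Best amplicon by primer mismatch count, or UNASSIGNED on tie/miss."""
    best_name = UNASSIGNED
    best = None
    tie = False
    for amp in panel:
        primer = amp.fwd_primer if side == "fwd" else amp.rev_primer
        if len(trimmed_prefix) < len(primer):
            continue
        d = hamming(trimmed_prefix[: len(primer)], primer)
        if best is None or d < best:
            best, best_name, tie = d, amp.name, False
        elif d == best:
            tie = True
    if best is None or best > max_primer_mismatch or tie:
        return UNASSIGNED, best if best is not None else -1
    return best_name, best


def quality_trim_index(quals: list[int], min_qual: int = 20, window: int = 4) -> int:
    """3' trim point: cut at the first base below ``min_qual`` after the last
    sliding window of mean ≥ ``min_qual``, then strip any remaining trailing
    bases below ``min_qual``.  Returns the kept length."""
    n = len(quals)
    if n == 0:
        return 0
    last_ok = -1
    if n >= window:
        s = sum(quals[:window])
        if s >= min_qual * window:
            last_ok = window - 1
        for i in range(1, n - window + 1):
            s += quals[i + window - 1] - quals[i - 1]
            if s >= min_qual * window:
                last_ok = i + window - 1
    cut = n
    for i in range(last_ok + 1, n):
        if quals[i] < min_qual:
            cut = i
            break
    while cut > 0 and quals[cut - 1] < min_qual:
        cut -= 1
    return cut


def _read_fastq_gz(path: str | Path) -> Iterator[tuple[str, str, list[int]]]:
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        for title, seq, qual in FastqGeneralIterator(fh):
            yield title.split()[0], seq, [ord(c) - PHRED_OFFSET for c in qual]


class _DemuxCache:
    """Memoised barcode/primer lookups (observed prefixes repeat heavily)."""

    def __init__(self, sheet: SampleSheet, panel: AmpliconPanel,
                 max_barcode_mismatch: int, max_primer_mismatch: int) -> None:
        self.sheet = sheet
        self.panel = panel
        self.bmm = max_barcode_mismatch
        self.pmm = max_primer_mismatch
        self._bc: dict[tuple[str, str], list[tuple[str, int]]] = {}
        self._amp: dict[tuple[str, str], tuple[str, int]] = {}
        self.max_primer_len = max(
            max(len(a.fwd_primer), len(a.rev_primer)) for a in panel
        )

    def barcode(self, prefix: str, side: str) -> list[tuple[str, int]]:
        key = (prefix, side)
        if key not in self._bc:
            self._bc[key] = match_barcode(prefix, self.sheet, self.bmm, side)
        return self._bc[key]

    def amplicon(self, prefix: str, side: str) -> tuple[str, int]:
        prefix = prefix[: self.max_primer_len]
        key = (prefix, side)
        if key not in self._amp:
            self._amp[key] = assign_amplicon(prefix, self.panel, self.pmm, side)
        return self._amp[key]


def demultiplex_pair(
    pair: ReadPair,
    sheet: SampleSheet,
    panel: AmpliconPanel,
    max_barcode_mismatch: int = 1,
    max_primer_mismatch: int = 2,
    trim_qual: int = 20,
    _cache: "_DemuxCache | None" = None,
) -> DemuxResult:
    """Assign a single read pair; see module docstring for the rules."""
    if _cache is None:
        _cache = _DemuxCache(sheet, panel, max_barcode_mismatch, max_primer_mismatch)
    if len(pair.seq1) < BARCODE_LEN or len(pair.seq2) < BARCODE_LEN:
        return DemuxResult(pair.id, UNASSIGNED, UNASSIGNED, -1, -1, pair, "too_short")

    cand1 = _cache.barcode(pair.seq1[:BARCODE_LEN], "fwd")
    cand2 = _cache.barcode(pair.seq2[:BARCODE_LEN], "rev")
    if len(cand1) != 1 or len(cand2) != 1:
        reason = "barcode_ambiguous" if len(cand1) > 1 or len(cand2) > 1 else "barcode_unmatched"
        return DemuxResult(pair.id, UNASSIGNED, UNASSIGNED, -1, -1, pair, reason)
    (s1, d1), (s2, d2) = cand1[0], cand2[0]
    if s1 != s2:
        return DemuxResult(pair.id, UNASSIGNED, UNASSIGNED, d1 + d2, -1, pair, "barcode_combination")

    amp1, pm1 = _cache.amplicon(pair.seq1[BARCODE_LEN:], "fwd")
    amp2, pm2 = _cache.amplicon(pair.seq2[BARCODE_LEN:], "rev")
    if amp1 == UNASSIGNED:
        return DemuxResult(pair.id, s1, UNASSIGNED, d1 + d2, pm1, pair, "primer_unmatched")
    if amp2 != UNASSIGNED and amp2 != amp1:
        return DemuxResult(pair.id, s1, UNASSIGNED, d1 + d2, pm1 + pm2, pair, "primer_conflict")
    amp = panel.get(amp1)

    k1 = quality_trim_index(pair.qual1, trim_qual)
    k2 = quality_trim_index(pair.qual2, trim_qual)
    t1 = BARCODE_LEN + len(amp.fwd_primer)
    t2 = BARCODE_LEN + len(amp.rev_primer)
    if k1 <= t1 or k2 <= t2:
        return DemuxResult(pair.id, s1, amp1, d1 + d2, pm1, pair, "too_short")
    trimmed = ReadPair(
        pair.id,
        pair.seq1[t1:k1], pair.seq2[t2:k2],
        pair.qual1[t1:k1], pair.qual2[t2:k2],
    )
    return DemuxResult(pair.id, s1, amp1, d1 + d2, pm1, trimmed)


def demultiplex_pool(
    r1: str | Path,
    r2: str | Path,
    sheet: SampleSheet,
    panel: AmpliconPanel,
    max_barcode_mismatch: int = 1,
    max_primer_mismatch: int = 2,
    trim_qual: int = 20,
    out_dir: str | Path | None = None,
) -> tuple[list[DemuxResult], CoverageReport]:
    """Demultiplex a paired FASTQ pool.

    When ``out_dir`` is given, assigned pairs are written to
    ``<sample>.<amplicon>.R{1,2}.fastq.gz`` and unassigned pairs to
    ``UNASSIGNED.R{1,2}.fastq.gz``.  Mates must arrive in the same order with
    matching ids; desynchronised input is a hard error.
    """
    results: list[DemuxResult] = []
    counts: dict[tuple[str, str], int] = {}
    reasons: dict[str, int] = {}
    writers: dict[tuple[str, str], tuple] = {}
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)

    def _writer(sample: str, ampname: str):
        key = (sample, ampname)
        if key not in writers:
            safe = ampname.replace("/", "_")
            stem = f"{sample}.{safe}" if sample != UNASSIGNED else UNASSIGNED
            writers[key] = (
                gzip.open(out_path / f"{stem}.R1.fastq.gz", "wt"),
                gzip.open(out_path / f"{stem}.R2.fastq.gz", "wt"),
            )
        return writers[key]

    cache = _DemuxCache(sheet, panel, max_barcode_mismatch, max_primer_mismatch)
    total = assigned = 0
    it2 = _read_fastq_gz(r2)
    try:
        for id1, seq1, qual1 in _read_fastq_gz(r1):
            try:
                id2, seq2, qual2 = next(it2)
            except StopIteration:
                raise ValueError("mate files desynchronised: R2 exhausted early")
            if id1 != id2:
                raise ValueError(f"mate files desynchronised at {id1} / {id2}")
            total += 1
            res = demultiplex_pair(
                ReadPair(id1, seq1, seq2, qual1, qual2),
                sheet, panel, max_barcode_mismatch, max_primer_mismatch, trim_qual,
                _cache=cache,
            )
            results.append(res)
            if res.sample_id != UNASSIGNED and res.amplicon != UNASSIGNED:
                assigned += 1
                counts[(res.sample_id, res.amplicon)] = counts.get((res.sample_id, res.amplicon), 0) + 1
            else:
                reasons[res.reason] = reasons.get(res.reason, 0) + 1
            if out_path is not None:
                key = (res.sample_id, res.amplicon)
                if UNASSIGNED in key:
                    key = (UNASSIGNED, UNASSIGNED)
                w1, w2 = _writer(*key)
                p = res.pair
                q1 = "".join(chr(q + PHRED_OFFSET) for q in p.qual1)
                q2 = "".join(chr(q + PHRED_OFFSET) for q in p.qual2)
                w1.write(f"@{p.id}\n{p.seq1}\n+\n{q1}\n")
                w2.write(f"@{p.id}\n{p.seq2}\n+\n{q2}\n")
        try:
            next(it2)
            raise ValueError("mate files desynchronised: R1 exhausted early")
        except StopIteration:
            pass
    finally:
        for w1, w2 in writers.values():
            w1.close()
            w2.close()

    samples = sheet.samples
    ampnames = [a.name for a in panel]
    mat = pd.DataFrame(0, index=samples, columns=ampnames, dtype=int)
    for (s, a), c in counts.items():
        mat.loc[s, a] = c
    report = CoverageReport(
        pair_counts=mat,
        total=total,
        assigned=assigned,
        unassigned=total - assigned,
        unassigned_reasons=reasons,
    )
    return results, report
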