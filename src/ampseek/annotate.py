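"""Codon-effect annotation and resistance-marker reporting.

Maps each filtered variant from amplicon coordinates through the panel's
gene models to a codon-level effect (synonymous / missense / nonsense /
frameshift / in-frame indel / non-coding), using the standard genetic code,
honouring strand and the codon offset of the gene fragment each amplicon
covers.  Known resistance markers are matched on (gene, native codon,
alternate amino acid) and reported with cross-species ortholog numbering
(e.g. vgsc L958F = L1014F in *M. domestica*; rdl A296S = A301S in
*D. melanogaster*).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio.Seq import Seq

from .panel_model import (
    Amplicon,
    AmpliconPanel,
    GeneModel,
    ResistanceMarker,
    marker_site,
    revcomp,
)
from .pileup_caller import FilterConfig, GenotypeCall, PileupMatrix, _BASE_IDX

_COMP = str.maketrans("ACGT", "TGCA")


@dataclass
class Annotation:
    """Codon-level effect of one variant."""

    key: tuple[str, int, str, str]       # amplicon, pos, ref, alt
    gene: str
    effect: str
    codon_number: int | None = None      # native numbering, coding effects only
    ref_aa: str | None = None
    alt_aa: str | None = None
    ortholog_labels: dict[str, str] = field(default_factory=dict)
    marker_hit: ResistanceMarker | None = None
    composite: bool = False              # variant overlaps a CDS boundary

    @property
    def aa_change(self) -> str:
        if self.codon_number is None:
            return "."
        return f"{self.ref_aa}{self.codon_number}{self.alt_aa}"


def _cds_map(amplicon: Amplicon, gm: GeneModel) -> tuple[str, list[int]]:
    """CDS sequence (gene orientation) and contig position of each CDS base."""
    parts: list[str] = []
    positions: list[int] = []
    contig_seq = amplicon.reference_seq
    off = amplicon.genomic_offset
    if gm.strand == "+":
        for s, e in gm.cds_intervals:
            parts.append(contig_seq[s - off: e - off])
            positions.extend(range(s, e))
    else:
        for s, e in reversed(gm.cds_intervals):
            parts.append(revcomp(contig_seq[s - off: e - off]))
            positions.extend(range(e - 1, s - 1, -1))
    return "".join(parts), positions


def annotate_variant(
    key: tuple[str, int, str, str],
    panel: AmpliconPanel,
) -> Annotation:
    """Annotate a single variant key (amplicon, 0-based pos, ref, alt).

    Substitutions are translated through the gene model to ref/alt amino
    acids; indels are frameshift unless their length is a multiple of three;
    positions outside any modelled CDS are non-coding.  Variants straddling a
    CDS boundary are flagged composite rather than dropped.
    """
    amp_name, pos, ref, alt = key
    amp = panel.get(amp_name)
    gm = panel.gene_models.get(amp_name)
    gene = gm.gene if gm is not None else amp.target_locus
    if gm is None:
        return Annotation(key, gene, "non_coding")

    cds_seq, cds_positions = _cds_map(amp, gm)
    pos_to_cds = {p: i for i, p in enumerate(cds_positions)}
    contig_positions = range(amp.genomic_offset + pos, amp.genomic_offset + pos + len(ref))
    in_cds = [p in pos_to_cds for p in contig_positions]
    if not any(in_cds):
        return Annotation(key, gene, "non_coding")
    composite = not all(in_cds)

    if len(ref) != len(alt):
        # single-event indel, VCF-anchored: net length change decides frame
        delta = len(alt) - len(ref)
        effect = "inframe_indel" if delta % 3 == 0 else "frameshift"
        anchor_cds = next(
            (pos_to_cds[p] for p in contig_positions if p in pos_to_cds), None
        )
        codon_number = gm.codon_offset + anchor_cds // 3 if anchor_cds is not None else None
        return Annotation(key, gene, effect, codon_number, composite=composite)

    # substitution(s): translate affected codons
    anns: list[tuple[int, str, str]] = []
    cds_alt = list(cds_seq)
    for i, p in enumerate(contig_positions):
        if p not in pos_to_cds:
            continue
        b = alt[i] if gm.strand == "+" else alt[i].translate(_COMP)
        cds_alt[pos_to_cds[p]] = b
    cds_alt = "".join(cds_alt)
    touched = sorted({pos_to_cds[p] // 3 for p in contig_positions if p in pos_to_cds})
    effect = "synonymous"
    codon_number = ref_aa = alt_aa = None
    for ci in touched:
        codon_ref = cds_seq[3 * ci: 3 * ci + 3]
        codon_alt = cds_alt[3 * ci: 3 * ci + 3]
        if len(codon_ref) < 3:
            composite = True
            continue
        ra = str(Seq(codon_ref).translate())
        aa = str(Seq(codon_alt).translate())
        if ra != aa:
            this = "nonsense" if aa == "*" else "missense"
            # the first amino-acid-changing codon defines the reported change
            if effect == "synonymous":
                effect, codon_number, ref_aa, alt_aa = this, gm.codon_offset + ci, ra, aa
        elif codon_number is None:
            codon_number, ref_aa, alt_aa = gm.codon_offset + ci, ra, aa
    ortho = gm.ortholog_label(codon_number, ref_aa, alt_aa) if codon_number else {}
    marker_hit = None
    if effect in ("missense", "nonsense"):
        for m in panel.markers:
            if (m.gene, m.native_codon, m.alt_aa) == (gene, codon_number, alt_aa):
                marker_hit = m
                break
    return Annotation(key, gene, effect, codon_number, ref_aa, alt_aa, ortho,
                      marker_hit, composite)


def annotate_calls(
    calls: dict[str, list[GenotypeCall]],
    panel: AmpliconPanel,
) -> dict[tuple, Annotation]:
    """Annotate every distinct variant key appearing in per-sample calls."""
    out: dict[tuple, Annotation] = {}
    for gcalls in calls.values():
        for gc in gcalls:
            if gc.call.key not in out:
                out[gc.call.key] = annotate_variant(gc.call.key, panel)
    return out


def genotype_at_site(
    p: PileupMatrix,
    pos: int,
    ref: str,
    alt: str,
    cfg: FilterConfig | None = None,
) -> str | None:
    """Genotype a sample directly from its pileup at a known site.

    Used for marker reporting so homozygous-reference samples (which emit no
    variant call) still enter the genotyped denominator.  Returns None when
    depth at the site is below the minimum (no call).
    """
    cfg = cfg or FilterConfig()
    if len(ref) != 1 or len(alt) != 1:
        raise ValueError("direct site genotyping supports substitutions only")
    if p.depth(pos) < cfg.min_depth:
        return None
    ad_ref = int(p.counts[pos, _BASE_IDX[ref]])
    ad_alt = int(p.counts[pos, _BASE_IDX[alt]])
    if ad_ref + ad_alt == 0:
        return None
    f = ad_alt / (ad_ref + ad_alt)
    if f < cfg.het_low:
        return "hom_ref"
    if f > cfg.het_high:
        return "hom_alt"
    return "het"


def resistance_report(
    pileups: dict[tuple[str, str], PileupMatrix],
    panel: AmpliconPanel,
    cfg: FilterConfig | None = None,
) -> pd.DataFrame:
    """Per-marker carrier counts, percentages and allele frequencies.

    For each catalogued marker every sample with sufficient depth at the
    marker site is genotyped with the 25/75 rule; carriers are het or hom_alt
    samples, the allele frequency is (het + 2·hom_alt) / (2·genotyped), and
    the genotyped denominator is printed beside every percentage.
    """
    cfg = cfg or FilterConfig()
    rows = []
    for m in panel.markers:
        try:
            amp_name, pos, ref, alt = marker_site(panel, m)
        except KeyError:
            continue
        genos: dict[str, str] = {}
        for (sample_id, amp), p in pileups.items():
            if amp != amp_name:
                continue
            g = genotype_at_site(p, pos, ref, alt, cfg)
            if g is not None:
                genos[sample_id] = g
        n_geno = len(genos)
        het = sum(g == "het" for g in genos.values())
        hom = sum(g == "hom_alt" for g in genos.values())
        carriers = het + hom
        rows.append({
            "marker": m.native_label,
            "gene": m.gene,
            "ortholog_label": m.ortholog_label,
            "carriers": carriers,
            "genotyped": n_geno,
            "carrier_pct": 100.0 * carriers / n_geno if n_geno else float("nan"),
            "allele_frequency": (het + 2 * hom) / (2 * n_geno) if n_geno else float("nan"),
            "het": het,
            "hom_alt": hom,
        })
    return pd.DataFrame(rows)


def write_marker_report(report: pd.DataFrame, path: str | Path) -> None:
    out = report.copy()
    out["carrier_pct"] = out["carrier_pct"].map(lambda v: f"{v:.1f}")
    out["allele_frequency"] = out["allele_frequency"].map(lambda v: f"{v:.4f}")
    out.to_csv(path, sep="\t", index=False)


def write_annotated_vcf_info(annotations: dict[tuple, Annotation]) -> dict[tuple, str]:
    """ANN-style INFO subfields (effect|gene|codon|aa_change) per variant key."""
    out = {}
    for key, a in annotations.items():
        codon = a.codon_number if a.codon_number is not None else "."
        out[key] = f"ANN={a.effect}|{a.gene}|{codon}|{a.aa_change}"
    return out
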