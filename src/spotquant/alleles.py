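"""Indel calling and protein-consequence annotation for ZFN alleles.

Targeted nuclease screens yield short amplicon reads of mutant alleles
that differ from the wild-type target region by a single contiguous indel.
This module calls that indel by flank alignment (leftmost placement by
default, HGVS-style rightmost available), translates the region in the
anchored reading frame, and derives the protein consequence:

* an indel length not divisible by 3 shifts the frame — reported as
  ``<refAA><pos><altAA>fsX<k>`` where k counts residues from the first
  altered residue (=1) to the new stop inclusive;
* a length divisible by 3 deletes whole residues — reported as
  ``<AA><pos>del`` (or a ``<AA><pos>_<AA><pos>del`` run), resolved by a
  protein-level diff so deletions straddling codon boundaries are named
  correctly.

Coordinates: ``position_nt`` is the coding-sequence (cds) coordinate of
the first affected base, 1-based; protein positions are absolute,
anchored by the first complete codon of the region.  Mutant amplicons may
read through the 3' end of the wild-type region into downstream coding
sequence; that readthrough tail is retained on the call so applying a
call to the wild-type sequence reproduces the mutant string exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import Seq

VALID_BASES = frozenset("ACGT")

#: Minimum matching right-flank length (nt) required before a call may
#: attribute remaining mutant sequence to 3' readthrough past the region.
MIN_READTHROUGH_FLANK = 6


class NoVariantError(ValueError):
    """The mutant sequence is identical to the wild-type region."""


class ComplexAlleleError(ValueError):
    """More than one contiguous difference between mutant and wild type."""


@dataclass
class TargetRegion:
    """A printed stretch of coding sequence with its frame anchor."""

    sequence: str
    cds_start_nt: int = 729
    frame_offset: int = 1
    first_residue_number: int = 244
    first_residue: str = "S"

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        _validate_bases(self.sequence)
        if self.frame_offset not in (0, 1, 2):
            raise ValueError("frame_offset must be 0, 1 or 2")
        first = translate_region(self, self.sequence)[:1]
        if first != self.first_residue:
            raise ValueError(
                f"frame anchor inconsistent: first complete codon encodes "
                f"{first!r}, expected {self.first_residue!r}"
            )


@dataclass
class IndelCall:
    """A single contiguous nucleotide-level difference against wild type."""

    kind: str  # deletion | insertion | delins
    ref_allele: str  # deleted bases ("" for pure insertion)
    alt_allele: str  # inserted bases ("" for pure deletion)
    position_nt: int  # cds coordinate of first affected base, 1-based
    length_nt: int  # length of the deleted (or inserted) tract
    alignment_policy: str = "leftmost"
    region_offset: int = 0  # 0-based offset of the event within the region
    tail_3prime: str = ""  # mutant readthrough beyond the wild-type region

    def apply(self, wild_type: str) -> str:
        """Reconstruct the mutant sequence from the wild type."""
        s = self.region_offset
        out = wild_type[:s] + self.alt_allele + wild_type[s + len(self.ref_allele):]
        return out + self.tail_3prime


@dataclass
class ProteinConsequence:
    """Predicted effect of an indel on the encoded protein."""

    kind: str  # frameshift | inframe_deletion | synonymous | missense | nonsense
    notation: str
    first_affected_residue: int | None
    fs_stop_offset: int | None  # None for non-frameshifts or stop beyond region
    mutant_peptide: str  # from first altered residue through the stop, if any


def _validate_bases(sequence: str) -> None:
    for i, b in enumerate(sequence):
        if b not in VALID_BASES:
            raise ValueError(f"non-ACGT character {b!r} at position {i + 1}")


def _common_prefix(a: str, b: str) -> int:
    n = min(len(a), len(b))
    for i in range(n):
        if a[i] != b[i]:
            return i
    return n


def call_indel(
    wild_type: TargetRegion, mutant_sequence: str, policy: str = "leftmost"
) -> IndelCall:
    """Call the single contiguous indel separating mutant from wild type.

    The mutant must match the wild-type region on both flanks of one
    event; anything beyond the 3' end of the wild-type region is recorded
    as readthrough tail.  Ambiguous placements within repeats resolve by
    ``policy`` ("leftmost" or "rightmost").  Raises
    :class:`NoVariantError` for identical sequences and
    :class:`ComplexAlleleError` for multiple differences.
    """
    if policy not in ("leftmost", "rightmost"):
        raise ValueError(f"unknown alignment policy {policy!r}")
    wt = wild_type.sequence
    mut = mutant_sequence.upper()
    _validate_bases(mut)
    if mut == wt:
        raise NoVariantError("no variant: mutant is identical to wild type")
    if mut.startswith(wt):
        raise NoVariantError(
            "no variant within the target region (3' readthrough only)"
        )

    p = _common_prefix(wt, mut)

    def fits(del_len: int, ins_len: int) -> tuple[str, str] | None:
        """Does mutant = wt[:p] + mut-insert + wt[p+del_len:] (+ tail)?

        Returns (rest, tail) when the remainder of the wild-type region
        reappears in the mutant right after the replaced block; the tail
        is 3' readthrough past the region and needs a real flank match.
        """
        rest = wt[p + del_len:]
        if not mut[p + ins_len:].startswith(rest):
            return None
        tail = mut[p + ins_len + len(rest):]
        if tail and len(rest) < MIN_READTHROUGH_FLANK:
            return None  # too little right flank to support a readthrough call
        return rest, tail

    # Most parsimonious single event first: scan by total edit size,
    # preferring pure indels over delins and deletions over insertions.
    max_d = max(len(wt) - p, len(mut) - p)
    for total in range(1, 2 * max_d + 1):
        # pure deletion of `total`
        if total <= len(wt) - p:
            hit = fits(total, 0)
            if hit is not None:
                return _place(wt, mut, "deletion", p, wt[p:p + total], "", total, policy, hit[1], wild_type)
        # pure insertion of `total`
        if total <= len(mut) - p:
            hit = fits(0, total)
            if hit is not None:
                return _place(wt, mut, "insertion", p, "", mut[p:p + total], total, policy, hit[1], wild_type)
        # delins with del_len + ins_len == total
        for del_len in range(1, total):
            ins_len = total - del_len
            if del_len > len(wt) - p or ins_len > len(mut) - p:
                continue
            hit = fits(del_len, ins_len)
            if hit is not None:
                ref_block, alt_block = wt[p:p + del_len], mut[p:p + ins_len]
                if del_len == ins_len and any(
                    a == b for a, b in zip(ref_block, alt_block)
                ):
                    # A same-length block agreeing at interior positions is
                    # multiple substitutions, not one contiguous event.
                    break
                return IndelCall(
                    kind="delins",
                    ref_allele=wt[p:p + del_len],
                    alt_allele=mut[p:p + ins_len],
                    position_nt=wild_type.cds_start_nt + p,
                    length_nt=del_len,
                    alignment_policy=policy,
                    region_offset=p,
                    tail_3prime=hit[1],
                )
    # Locate the two mismatch loci for the error message.
    q = _common_prefix(wt[::-1], mut[::-1])
    raise ComplexAlleleError(
        f"complex allele: differences near cds nt {wild_type.cds_start_nt + p} "
        f"and cds nt {wild_type.cds_start_nt + len(wt) - 1 - q}"
    )


def _place(
    wt: str,
    mut: str,
    kind: str,
    s: int,
    ref: str,
    alt: str,
    d: int,
    policy: str,
    tail: str,
    region: TargetRegion,
) -> IndelCall:
    """Shift an indel through its repeat context per the alignment policy."""
    if kind == "deletion":
        if policy == "leftmost":
            while s > 0 and wt[s - 1] == wt[s + d - 1]:
                s -= 1
        else:
            while s + d < len(wt) and wt[s] == wt[s + d]:
                s += 1
        ref = wt[s:s + d]
    else:  # insertion
        ins = alt
        if policy == "leftmost":
            while s > 0 and wt[s - 1] == ins[-1]:
                s -= 1
                ins = ins[-1] + ins[:-1]
        else:
            while s < len(wt) and wt[s] == ins[0]:
                ins = ins[1:] + ins[0]
                s += 1
        alt = ins
    call = IndelCall(
        kind=kind,
        ref_allele=ref,
        alt_allele=alt,
        position_nt=region.cds_start_nt + s,
        length_nt=d,
        alignment_policy=policy,
        region_offset=s,
        tail_3prime=tail,
    )
    if call.apply(wt) != mut:
        raise ComplexAlleleError("internal placement error: call does not round-trip")
    return call


def translate_region(region: TargetRegion, sequence: str) -> str:
    """Translate complete codons from the region's frame anchor.

    A trailing partial codon is dropped; translation runs through the
    first stop codon, which is included as ``*``.
    """
    seq = sequence.upper()
    _validate_bases(seq)
    coding = seq[region.frame_offset:]
    coding = coding[: len(coding) // 3 * 3]
    if not coding:
        raise ValueError("sequence too short to contain one complete codon")
    protein = str(Seq(coding).translate())
    stop = protein.find("*")
    return protein[: stop + 1] if stop != -1 else protein


def protein_consequence(
    region: TargetRegion, indel: IndelCall, mutant_sequence: str
) -> ProteinConsequence:
    """Derive the protein-level effect of a called indel.

    Frameshifts are annotated from the first residue at which the mutant
    translation diverges; in-frame deletions by a longest-common-flank
    protein diff, which resolves codon-boundary-straddling deletions to
    the residue(s) actually lost.
    """
    wt_protein = translate_region(region, region.sequence)
    mut_protein = translate_region(region, mutant_sequence.upper())
    base = region.first_residue_number
    net = len(indel.alt_allele) - len(indel.ref_allele)

    if net % 3 != 0:
        i = _common_prefix(wt_protein, mut_protein)
        if i >= len(mut_protein):
            raise ValueError("mutant translation ends before diverging from wild type")
        ref_aa = wt_protein[i] if i < len(wt_protein) else "?"
        alt_aa = mut_protein[i]
        r = base + i
        stop = mut_protein.find("*", i)
        if stop == -1:
            return ProteinConsequence(
                kind="frameshift",
                notation=f"{ref_aa}{r}{alt_aa}fs",
                first_affected_residue=r,
                fs_stop_offset=None,  # stop lies beyond the sequenced region
                mutant_peptide=mut_protein[i:],
            )
        k = stop - i + 1
        return ProteinConsequence(
            kind="frameshift",
            notation=f"{ref_aa}{r}{alt_aa}fsX{k}",
            first_affected_residue=r,
            fs_stop_offset=k,
            mutant_peptide=mut_protein[i:stop + 1],
        )

    # In-frame: protein-level diff with leftmost placement, consistent
    # with the nucleotide default.  Compare only over the wild-type
    # region's translated extent so 3' readthrough does not mask the
    # local event.
    wtp = wt_protein
    mutp = mut_protein[: len(wtp) + net // 3] if net < 0 else mut_protein
    if wtp == mutp:
        return ProteinConsequence("synonymous", "=", None, None, "")
    lw, lm = len(wtp), len(mutp)
    if lm < lw:  # net residue loss: try a pure deletion, leftmost
        k = lw - lm
        for s in range(lw - k + 1):
            if wtp[:s] == mutp[:s] and wtp[s + k:] == mutp[s:]:
                deleted = wtp[s:s + k]
                r = base + s
                if k == 1:
                    notation = f"{deleted}{r}del"
                else:
                    notation = f"{deleted[0]}{r}_{deleted[-1]}{r + k - 1}del"
                return ProteinConsequence("inframe_deletion", notation, r, None, "")
    if lm > lw:  # net residue gain: try a pure insertion, leftmost
        k = lm - lw
        for s in range(lw + 1):
            if wtp[:s] == mutp[:s] and mutp[s + k:] == wtp[s:]:
                inserted = mutp[s:s + k]
                left = f"{wtp[s - 1]}{base + s - 1}" if s else "start"
                right = f"{wtp[s]}{base + s}" if s < lw else "end"
                return ProteinConsequence(
                    "inframe_insertion", f"{left}_{right}ins{inserted}", base + s, None, inserted
                )
    # No clean single event: report the replaced block between the
    # longest common flanks.
    p = _common_prefix(wtp, mutp)
    q = _common_prefix(wtp[::-1], mutp[::-1])
    q = min(q, lw - p, lm - p)
    deleted, inserted = wtp[p:lw - q], mutp[p:lm - q]
    if len(deleted) == 1 and len(inserted) == 1:
        kind = "nonsense" if inserted == "*" else "missense"
        return ProteinConsequence(kind, f"{deleted}{base + p}{inserted}", base + p, None, inserted)
    notation = (
        f"{deleted[0]}{base + p}_{deleted[-1]}{base + p + len(deleted) - 1}delins{inserted}"
    )
    return ProteinConsequence("missense", notation, base + p, None, inserted)
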