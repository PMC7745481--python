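"""Paired multiple sequence alignments ("dimers").

A dimer is a pair of protein-family alignments whose rows are matched
one-to-one by species and listed in the same order, so that row *i* of
both families comes from the same organism.  This matching is what makes
inter-protein column covariation meaningful: co-occurring residues on
row *i* were exposed to the same evolutionary history.

Sequences use a fixed 21-letter alphabet (20 amino acids plus ``-`` for
gaps).  The gap is counted as an ordinary 21st symbol downstream, so
readers map ambiguity codes (B, Z, X, U, O, J) onto the gap symbol
rather than inventing extra states.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Literal, Optional, Sequence

import numpy as np
from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

RESIDUES = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
ALPHABET = RESIDUES + GAP
GAP_CODE = ALPHABET.index(GAP)  # 20
N_SYMBOLS = len(ALPHABET)  # 21

#: letters with no unambiguous amino-acid identity; folded into the gap
#: symbol so the alphabet stays exactly 21 states.  ``.`` is accepted as
#: an alternative gap spelling.
AMBIGUOUS = "BZXUOJ"
_SANITIZE = str.maketrans(
    {c: GAP for c in AMBIGUOUS}
    | {c: GAP for c in AMBIGUOUS.lower()}
    | {".": GAP}
)

MsaFormat = Literal["fasta", "clustal"]


class MsaError(ValueError):
    """Raised for malformed or inconsistent alignment input."""


def sanitize_sequence(seq: str) -> str:
    """Uppercase a sequence and fold ambiguity codes into the gap symbol.

    Raises :class:`MsaError` on characters outside the 21-letter alphabet
    after the mapping.
    """
    s = seq.upper().translate(_SANITIZE)
    bad = sorted(set(s) - set(ALPHABET))
    if bad:
        raise MsaError(f"illegal sequence characters: {bad!r}")
    return s


@dataclass
class AlignedFamily:
    """One aligned protein family.

    ``sequences`` are equal-length strings over the 21-letter alphabet;
    ``species`` carries one organism label per row in the same order.
    ``query_index`` points at the query sequence, which must be gap-free
    (gap columns at the query are removed upstream, so alignment width
    equals query length).
    """

    family_id: str
    sequences: list[str]
    species: list[str]
    query_index: int = 0

    def __post_init__(self) -> None:
        if not self.sequences:
            raise MsaError(f"{self.family_id}: empty alignment")
        width = len(self.sequences[0])
        if width == 0:
            raise MsaError(f"{self.family_id}: zero-width alignment")
        for k, s in enumerate(self.sequences):
            if len(s) != width:
                raise MsaError(
                    f"{self.family_id}: ragged alignment (row {k} has length "
                    f"{len(s)}, expected {width})"
                )
            extra = set(s) - set(ALPHABET)
            if extra:
                raise MsaError(
                    f"{self.family_id}: row {k} contains characters outside "
                    f"the 21-letter alphabet: {sorted(extra)!r}"
                )
        if len(self.species) != len(self.sequences):
            raise MsaError(
                f"{self.family_id}: {len(self.species)} species labels for "
                f"{len(self.sequences)} sequences"
            )
        if not 0 <= self.query_index < len(self.sequences):
            raise MsaError(f"{self.family_id}: query_index out of range")
        if GAP in self.sequences[self.query_index]:
            raise MsaError(
                f"{self.family_id}: query sequence contains gap characters; "
                "query-gap columns must be removed upstream"
            )

    @property
    def width(self) -> int:
        return len(self.sequences[0])

    @property
    def n_sequences(self) -> int:
        return len(self.sequences)

    def to_codes(self) -> np.ndarray:
        """Encode as an (n_sequences, width) uint8 array, gap = 20."""
        flat = "".join(self.sequences).encode("ascii")
        arr = np.frombuffer(flat, dtype=np.uint8).reshape(
            self.n_sequences, self.width
        )
        lut = np.zeros(128, dtype=np.uint8)
        for i, c in enumerate(ALPHABET):
            lut[ord(c)] = i
        return lut[arr]


@dataclass
class PairedMSA:
    """A dimer: two families with identical species lists in identical order."""

    dimer_id: str
    family_a: AlignedFamily
    family_b: AlignedFamily
    label: Optional[str] = None  # "positive" | "negative" | None

    def __post_init__(self) -> None:
        a, b = self.family_a, self.family_b
        if a.n_sequences != b.n_sequences:
            raise MsaError(
                f"{self.dimer_id}: row count mismatch "
                f"({a.n_sequences} vs {b.n_sequences})"
            )
        if a.species != b.species:
            raise MsaError(f"{self.dimer_id}: species order mismatch")
        if a.query_index != b.query_index:
            raise MsaError(
                f"{self.dimer_id}: query row differs between families "
                f"({a.query_index} vs {b.query_index})"
            )
        if self.label not in (None, "positive", "negative"):
            raise MsaError(f"{self.dimer_id}: bad label {self.label!r}")

    @property
    def n(self) -> int:
        """Number of matched sequences (alignment depth N)."""
        return self.family_a.n_sequences


# --- species parsing -------------------------------------------------------

_BRACKET = re.compile(r"\[([^\]]+)\]")
_UNIPROT_OS = re.compile(r"\bOS=(.+?)(?:\s+[A-Z]{2}=|$)")


def default_species_rule(header: str) -> str:
    """Extract a species label from a sequence header.

    Tried in order: text in square brackets (NCBI style), the ``OS=``
    field (UniProt style), the token after the last ``|`` in the id, and
    finally the bare id token.
    """
    m = _BRACKET.search(header)
    if m:
        return m.group(1).strip()
    m = _UNIPROT_OS.search(header)
    if m:
        return m.group(1).strip()
    token = header.split()[0] if header.split() else header
    if "|" in token:
        return token.rsplit("|", 1)[1]
    return token


SpeciesRule = Callable[[str], str]

_QUERY_ID = re.compile(r"^q\d+\|")


def read_family(
    path: str | Path,
    format: MsaFormat = "fasta",
    family_id: Optional[str] = None,
    species_rule: SpeciesRule = default_species_rule,
) -> AlignedFamily:
    """Read one alignment from a FASTA or Clustal file.

    Rows are never reordered.  The query row is the one whose id carries
    the ``q<number>|`` marker written by :func:`write_family`; absent
    that marker the first row is taken as the query.
    """
    path = Path(path)
    if format not in ("fasta", "clustal"):
        raise MsaError(f"unsupported format {format!r}")
    try:
        aln = AlignIO.read(str(path), format)
    except ValueError as exc:
        raise MsaError(f"{path}: cannot parse as {format}: {exc}") from exc
    sequences, species = [], []
    query_index = 0
    for k, rec in enumerate(aln):
        header = rec.description if rec.description else rec.id
        sequences.append(sanitize_sequence(str(rec.seq)))
        species.append(species_rule(header))
        if _QUERY_ID.match(rec.id):
            query_index = k
    return AlignedFamily(
        family_id=family_id or path.stem,
        sequences=sequences,
        species=species,
        query_index=query_index,
    )


def read_paired_msa(
    path_a: str | Path,
    path_b: str | Path,
    format: MsaFormat = "fasta",
    dimer_id: Optional[str] = None,
    label: Optional[str] = None,
    species_rule: SpeciesRule = default_species_rule,
) -> PairedMSA:
    """Read and cross-validate the two alignments of one dimer."""
    fam_a = read_family(path_a, format, species_rule=species_rule)
    fam_b = read_family(path_b, format, species_rule=species_rule)
    return PairedMSA(
        dimer_id=dimer_id or f"{fam_a.family_id}__{fam_b.family_id}",
        family_a=fam_a,
        family_b=fam_b,
        label=label,
    )


def concatenate_pair(p: PairedMSA) -> AlignedFamily:
    """Row-wise concatenation of the two families (for CCMpred input).

    Row *i* of the result is row *i* of family A followed by row *i* of
    family B; the width is the sum of the two widths and the species
    order is untouched.
    """
    seqs = [
        a + b
        for a, b in zip(p.family_a.sequences, p.family_b.sequences)
    ]
    return AlignedFamily(
        family_id=f"{p.dimer_id}_concat",
        sequences=seqs,
        species=list(p.family_a.species),
        query_index=p.family_a.query_index,
    )


def write_family(
    f: AlignedFamily, path: str | Path, format: MsaFormat = "fasta"
) -> None:
    """Write an alignment; read(write(f)) round-trips rows, order and species.

    Row ids are ``r<k>|<species>`` with ``q<k>|<species>`` marking the
    query row, so both the species label and the query position survive
    the Clustal format, which keeps only the id token.  Whitespace inside
    species labels is replaced by ``_`` (Clustal ids cannot contain
    spaces).
    """
    if format not in ("fasta", "clustal"):
        raise MsaError(f"unsupported format {format!r}")
    records = []
    for k, (seq, sp) in enumerate(zip(f.sequences, f.species)):
        tag = "q" if k == f.query_index else "r"
        safe_sp = re.sub(r"\s+", "_", sp)
        records.append(
            SeqRecord(Seq(seq), id=f"{tag}{k + 1:04d}|{safe_sp}", description="")
        )
    aln = MultipleSeqAlignment(records)
    AlignIO.write(aln, str(path), format)
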