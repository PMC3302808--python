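"""Aligned coding sequences: reading, validation, haplotype collapsing.

The central container is :class:`CodonAlignment`, an in-frame nucleotide
alignment with per-sample metadata, an optional outgroup used for
polarization, and named region annotations (e.g. the DM/OD1 domain versus the
remaining common region of *doublesex*).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from Bio import SeqIO

VALID_ALPHABET = frozenset("ACGTN-")

# byte codes used by the numeric matrix view
_CODE = {b: i for i, b in enumerate("ACGTN-")}
GAP_CODE, N_CODE = 5, 4


class AlignmentError(ValueError):
    pass


class FastaParseError(ValueError):
    pass


class FrameError(ValueError):
    pass


@dataclass(frozen=True)
class SampleSequence:
    sample_id: str
    seq: str
    species: str = ""
    locality: str = ""


@dataclass(frozen=True)
class Region:
    """Named nucleotide range, 1-based inclusive on the alignment."""

    name: str
    start: int
    end: int


@dataclass
class CodonAlignment:
    sequences: list[SampleSequence]
    frame_offset: int = 0
    outgroup: tuple[str, str] | None = None  # (id, seq)
    regions: list[Region] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sequences:
            raise AlignmentError("alignment has no sequences")
        L = len(self.sequences[0].seq)
        for rec in self.sequences:
            if len(rec.seq) != L:
                raise AlignmentError(
                    f"sequence {rec.sample_id!r} has length {len(rec.seq)}, expected {L}"
                )
            bad = set(rec.seq) - VALID_ALPHABET
            if bad:
                raise FastaParseError(
                    f"sequence {rec.sample_id!r} contains non-IUPAC characters {sorted(bad)}"
                )
        if self.outgroup is not None and len(self.outgroup[1]) != L:
            raise AlignmentError("outgroup length differs from alignment length")
        if not 0 <= self.frame_offset < 3:
            raise FrameError("frame_offset must be 0, 1 or 2")
        if (L - self.frame_offset) // 3 < 1:
            raise FrameError("frame offset leaves no complete codon")
        for r in self.regions:
            if not (1 <= r.start <= r.end <= L):
                raise AlignmentError(f"region {r.name} outside [1, {L}]")

    # ---- basic geometry -------------------------------------------------
    @property
    def length(self) -> int:
        return len(self.sequences[0].seq)

    @property
    def n(self) -> int:
        return len(self.sequences)

    @property
    def n_codons(self) -> int:
        return (self.length - self.frame_offset) // 3

    def codon_span(self, codon_index: int) -> tuple[int, int]:
        """1-based inclusive nt span of codon *codon_index* (0-based)."""
        start = self.frame_offset + 3 * codon_index + 1
        return start, start + 2

    def site_codon_index(self, site: int) -> int | None:
        """0-based codon index of 1-based nt *site*, None if out of frame."""
        idx = (site - 1 - self.frame_offset) // 3
        if site <= self.frame_offset or idx >= self.n_codons:
            return None
        return idx

    # ---- numeric views --------------------------------------------------
    def matrix(self, with_outgroup: bool = False) -> np.ndarray:
        """(n, L) uint8 matrix; A,C,G,T,N,- coded 0..5."""
        seqs = [r.seq for r in self.sequences]
        if with_outgroup:
            if self.outgroup is None:
                raise AlignmentError("no outgroup attached")
            seqs = seqs + [self.outgroup[1]]
        lut = np.full(128, 255, dtype=np.uint8)
        for b, c in _CODE.items():
            lut[ord(b)] = c
        return lut[np.frombuffer("".join(seqs).encode(), dtype=np.uint8).reshape(
            len(seqs), self.length
        )]

    def usable_sites(self, require_outgroup: bool = False) -> np.ndarray:
        """Boolean mask of columns free of '-' and 'N' in every analyzed sequence.

        Columns carrying a gap or an ambiguous base anywhere are excluded from
        all per-site statistics; with ``require_outgroup`` the outgroup row
        must be clean as well.
        """
        m = self.matrix(with_outgroup=require_outgroup and self.outgroup is not None)
        return (m < 4).all(axis=0)

    # ---- region handling ------------------------------------------------
    def region(self, name: str) -> Region:
        for r in self.regions:
            if r.name == name:
                return r
        raise KeyError(f"no region named {name!r}")

    def subset(self, region: str | Region) -> "CodonAlignment":
        """Restrict the alignment to one annotated region.

        The slice is snapped inward to complete codons so the subset stays in
        frame.
        """
        r = region if isinstance(region, Region) else self.region(region)
        first = (r.start - 1 - self.frame_offset + 2) // 3
        last = (r.end - self.frame_offset) // 3 - 1
        if last < first:
            raise FrameError(f"region {r.name} contains no complete codon")
        a = self.frame_offset + 3 * first
        b = self.frame_offset + 3 * (last + 1)
        new_seqs = [replace(s, seq=s.seq[a:b]) for s in self.sequences]
        og = None if self.outgroup is None else (self.outgroup[0], self.outgroup[1][a:b])
        return CodonAlignment(new_seqs, frame_offset=0, outgroup=og, regions=[])

    def complement(self, region: str | Region, name: str = "complement") -> "CodonAlignment":
        """Alignment restricted to the codons *outside* a region."""
        r = region if isinstance(region, Region) else self.region(region)
        first = (r.start - 1 - self.frame_offset + 2) // 3
        last = (r.end - self.frame_offset) // 3 - 1
        keep = [i for i in range(self.n_codons) if i < first or i > last]
        if not keep:
            raise FrameError("complement contains no codon")

        def pick(seq: str) -> str:
            return "".join(
                seq[self.frame_offset + 3 * i : self.frame_offset + 3 * i + 3] for i in keep
            )

        new_seqs = [replace(s, seq=pick(s.seq)) for s in self.sequences]
        og = None if self.outgroup is None else (self.outgroup[0], pick(self.outgroup[1]))
        return CodonAlignment(new_seqs, frame_offset=0, outgroup=og, regions=[])


@dataclass(frozen=True)
class Haplotype:
    hap_id: str
    seq: str
    count: int
    members: tuple[str, ...]
    species_set: frozenset[str]


@dataclass
class HaplotypeSet:
    haplotypes: list[Haplotype]

    @property
    def n(self) -> int:
        return sum(h.count for h in self.haplotypes)

    @property
    def h(self) -> int:
        return len(self.haplotypes)

    @property
    def counts(self) -> np.ndarray:
        return np.array([h.count for h in self.haplotypes])

    def by_id(self, hap_id: str) -> Haplotype:
        for h in self.haplotypes:
            if h.hap_id == hap_id:
                return h
        raise KeyError(hap_id)


def read_alignment(
    path,
    metadata=None,
    frame_offset: int = 0,
    outgroup_id: str | None = None,
    regions: list[Region] | None = None,
) -> CodonAlignment:
    """Read an aligned FASTA (plus optional TSV metadata) into a CodonAlignment.

    Metadata is joined on ``sample_id``; rows that match no FASTA record are
    reported via the returned alignment's being unaffected (a warning is
    printed) rather than raising.  ``outgroup_id`` pulls that record out of
    the sample set and attaches it as the polarization outgroup.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FastaParseError(f"no FASTA records in {path}")
    meta = {}
    if metadata is not None:
        df = pd.read_csv(metadata, sep="\t", dtype=str).fillna("")
        if "sample_id" not in df.columns:
            raise FastaParseError("metadata TSV must have a sample_id column")
        meta = {row["sample_id"]: row for _, row in df.iterrows()}
        unmatched = set(meta) - {r.id for r in records}
        if unmatched:
            print(f"[hapsel] metadata rows with no FASTA record: {sorted(unmatched)}")
    outgroup = None
    seqs = []
    for rec in records:
        s = str(rec.seq).upper()
        if rec.id == outgroup_id:
            outgroup = (rec.id, s)
            continue
        row = meta.get(rec.id, {})
        seqs.append(
            SampleSequence(
                sample_id=rec.id,
                seq=s,
                species=str(row.get("species", "")),
                locality=str(row.get("locality", "")),
            )
        )
    return CodonAlignment(
        seqs, frame_offset=frame_offset, outgroup=outgroup, regions=list(regions or [])
    )


def write_fasta(aln: CodonAlignment, path, include_outgroup: bool = True) -> None:
    with open(path, "w") as fh:
        for rec in aln.sequences:
            fh.write(f">{rec.sample_id}\n{rec.seq}\n")
        if include_outgroup and aln.outgroup is not None:
            fh.write(f">{aln.outgroup[0]}\n{aln.outgroup[1]}\n")


def collapse_haplotypes(aln: CodonAlignment) -> HaplotypeSet:
    """Group identical sequences into haplotypes.

    Grouping is exact string identity: sequences differing only by an 'N'
    against a resolved base are distinct haplotypes (no merging of partial
    information).  Identifiers are assigned deterministically: H1, H2, ... in
    order of descending count, ties broken by lexicographic sequence.
    """
    groups: dict[str, list[SampleSequence]] = {}
    for rec in aln.sequences:
        groups.setdefault(rec.seq, []).append(rec)
    ordered = sorted(groups.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    haps = [
        Haplotype(
            hap_id=f"H{i + 1}",
            seq=seq,
            count=len(members),
            members=tuple(m.sample_id for m in members),
            species_set=frozenset(m.species for m in members if m.species),
        )
        for i, (seq, members) in enumerate(ordered)
    ]
    return HaplotypeSet(haps)


def expand(hs: HaplotypeSet) -> list[str]:
    """Multiset of sequences represented by the haplotype set."""
    out: list[str] = []
    for h in hs.haplotypes:
        out.extend([h.seq] * h.count)
    return out


def alignment_from_strings(
    seqs: dict[str, str] | list[str],
    frame_offset: int = 0,
    outgroup: tuple[str, str] | None = None,
    regions: list[Region] | None = None,
    species: dict[str, str] | None = None,
) -> CodonAlignment:
    """Convenience constructor used throughout the tests and examples."""
    if isinstance(seqs, list):
        seqs = {f"s{i + 1}": s for i, s in enumerate(seqs)}
    species = species or {}
    recs = [
        SampleSequence(sample_id=k, seq=v.upper(), species=species.get(k, ""))
        for k, v in seqs.items()
    ]
    return CodonAlignment(
        recs, frame_offset=frame_offset, outgroup=outgroup, regions=list(regions or [])
    )
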