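"""Toy murine immunoglobulin germline gene-segment sets.

The murine light-chain loci have a highly asymmetric architecture: the Igk
locus carries >100 V genes and four functional J genes (five named, Igkj3
being a pseudogene), whereas the Igl locus is organised into two physical
cassettes of V genes linked to specific J-C units:

* cassette 1: Iglv2, Iglv3 upstream of Iglj2-Iglc2 (family lambda2)
* cassette 2: Iglv1 upstream of Iglj3-Iglc3 (lambda3) and Iglj1-Iglc1 (lambda1)

V-J recombination in the Igl locus stays within a cassette, so the J-C unit
(and therefore the lambda family) constrains which V genes can be used.

This module builds down-scaled germline sets that encode that topology
exactly while keeping V-gene counts small enough for exhaustive alignment.
Sequences are random coding-like DNA with implanted junction anchors (the
conserved V-region Cys codon and the J-region [FW]-G-x-G motif); gene
identity, not sequence content, carries all repertoire statistics.

Coordinates are 0-based; intervals are half-open.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class Locus(str, Enum):
    IGH = "IGH"
    IGK = "IGK"
    IGL = "IGL"


class SegmentClass(str, Enum):
    V = "V"
    D = "D"
    J = "J"
    C = "C"


#: lambda family implied by each Igl J(-C) unit.
LAMBDA_FAMILY_OF_J: dict[str, str] = {
    "Iglj1": "lambda1",
    "Iglj2": "lambda2",
    "Iglj3": "lambda3",
}

#: Igl cassette topology: cassette id -> (V names, J names in genomic order).
IGL_CASSETTES: dict[int, tuple[tuple[str, ...], tuple[str, ...]]] = {
    1: (("Iglv2", "Iglv3"), ("Iglj2",)),
    2: (("Iglv1",), ("Iglj3", "Iglj1")),
}

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

# geometry shared by generator and annotator; headroom after the V anchor
# and before the J anchor bounds exonuclease trimming so anchors survive.
V_LENGTH = 150
V_ANCHOR = 141          # codon-aligned Cys codon; 6 nt of 3' headroom
J_LENGTH = 48
J_ANCHOR = 12           # [FW] codon; 12 nt of 5' headroom
D_LENGTH = 12
C_LENGTH = 30


class GermlineError(ValueError):
    """Invalid germline set or segment."""


class GermlineFormatError(GermlineError):
    """Malformed germline FASTA record."""


@dataclass(frozen=True)
class GeneSegment:
    """One germline gene segment.

    ``anchor_offset`` is the 0-based nucleotide offset of the conserved
    junction-anchor codon: the Cys codon for V segments, the Trp/Phe codon
    of the [FW]-G-x-G motif for J segments; absent for D and C.
    """

    name: str
    locus: Locus
    segment_class: SegmentClass
    sequence: str
    cassette: int | None = None
    anchor_offset: int | None = None
    reading_frame: int = 0
    is_functional: bool = True

    def __post_init__(self) -> None:
        if not self.sequence or set(self.sequence) - set("ACGT"):
            raise GermlineError(
                f"{self.name}: sequence must be non-empty over A/C/G/T"
            )
        if self.anchor_offset is not None:
            if not (0 <= self.anchor_offset < len(self.sequence) - 2):
                raise GermlineError(f"{self.name}: anchor_offset out of range")
            if (self.anchor_offset - self.reading_frame) % 3 != 0:
                raise GermlineError(
                    f"{self.name}: anchor_offset not on a codon boundary"
                )

    @property
    def anchor_codon(self) -> str | None:
        if self.anchor_offset is None:
            return None
        return self.sequence[self.anchor_offset : self.anchor_offset + 3]

    def validate_anchor_motif(self) -> None:
        """V segments must carry Cys at the anchor; J segments [FW]G.G."""
        if self.segment_class is SegmentClass.V:
            if str(Seq(self.anchor_codon).translate()) != "C":
                raise GermlineError(f"{self.name}: V anchor codon is not Cys")
        elif self.segment_class is SegmentClass.J:
            motif_nt = self.sequence[self.anchor_offset : self.anchor_offset + 12]
            aa = str(Seq(motif_nt).translate())
            if len(aa) < 4 or aa[0] not in "FW" or aa[1] != "G" or aa[3] != "G":
                raise GermlineError(f"{self.name}: J anchor motif is not [FW]G.G")


@dataclass
class GermlineSet:
    """A collection of gene segments plus locus/cassette topology."""

    segments: dict[str, GeneSegment] = field(default_factory=dict)

    def add(self, seg: GeneSegment) -> None:
        if seg.name in self.segments:
            raise GermlineError(f"duplicate segment name {seg.name!r}")
        self.segments[seg.name] = seg

    def __getitem__(self, name: str) -> GeneSegment:
        return self.segments[name]

    def __contains__(self, name: str) -> bool:
        return name in self.segments

    def __len__(self) -> int:
        return len(self.segments)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GermlineSet):
            return NotImplemented
        return self.segments == other.segments

    def by_class(
        self, locus: Locus, segment_class: SegmentClass, functional_only: bool = False
    ) -> list[GeneSegment]:
        out = [
            s
            for s in self.segments.values()
            if s.locus is locus and s.segment_class is segment_class
        ]
        if functional_only:
            out = [s for s in out if s.is_functional]
        return sorted(out, key=lambda s: s.name)

    @property
    def locus_topology(self) -> dict[Locus, dict[SegmentClass, list[str]]]:
        topo: dict[Locus, dict[SegmentClass, list[str]]] = {}
        for locus in Locus:
            topo[locus] = {
                cls: [s.name for s in self.by_class(locus, cls)]
                for cls in SegmentClass
            }
        return topo

    @property
    def igl_cassettes(self) -> dict[int, tuple[tuple[str, ...], tuple[str, ...]]]:
        return IGL_CASSETTES

    @property
    def lambda_family_of(self) -> dict[str, str]:
        return LAMBDA_FAMILY_OF_J

    def validate(self) -> None:
        for seg in self.segments.values():
            if seg.segment_class in (SegmentClass.V, SegmentClass.J):
                if seg.anchor_offset is None:
                    raise GermlineError(f"{seg.name}: missing anchor_offset")
                seg.validate_anchor_motif()
            if seg.segment_class is SegmentClass.V:
                # no stop codon upstream of the anchor Cys
                frame = seg.reading_frame
                aa = str(
                    Seq(seg.sequence[frame : seg.anchor_offset]).translate()
                )
                if "*" in aa:
                    raise GermlineError(f"{seg.name}: stop codon before V anchor")
        igl_v = {s.name for s in self.by_class(Locus.IGL, SegmentClass.V)}
        igl_j = {s.name for s in self.by_class(Locus.IGL, SegmentClass.J)}
        cas_v = {v for vs, _ in IGL_CASSETTES.values() for v in vs}
        cas_j = {j for _, js in IGL_CASSETTES.values() for j in js}
        if igl_v and igl_v != cas_v:
            raise GermlineError("Igl V segments do not match cassette topology")
        if igl_j and igl_j != cas_j:
            raise GermlineError("Igl J segments do not match cassette topology")
        igkj = self.by_class(Locus.IGK, SegmentClass.J)
        if igkj:
            functional = [s.name for s in igkj if s.is_functional]
            if len(functional) != 4 or "Igkj3" in functional:
                raise GermlineError(
                    "Igk locus must have exactly 4 functional J genes "
                    "(Igkj3 is a pseudogene)"
                )


def cassette_of(gs: GermlineSet, v_name: str, j_name: str) -> str:
    """Classify an Igl V-J combination relative to the cassette topology.

    Returns ``"same_cassette"``, ``"cross_cassette"``, or ``"not_igl"`` when
    either gene lies outside the Igl locus. Unknown names raise ``KeyError``.
    """
    v = gs[v_name]
    j = gs[j_name]
    if v.locus is not Locus.IGL or j.locus is not Locus.IGL:
        return "not_igl"
    for vs, js in gs.igl_cassettes.values():
        if v_name in vs and j_name in js:
            return "same_cassette"
    return "cross_cassette"


# ---------------------------------------------------------------------------
# sequence generation
# ---------------------------------------------------------------------------

_NON_STOP_CODONS = sorted(
    "".join(c)
    for c in itertools.product("ACGT", repeat=3)
    if "".join(c) not in STOP_CODONS
)


def _random_codons(rng: np.random.Generator, n: int) -> str:
    idx = rng.integers(0, len(_NON_STOP_CODONS), size=n)
    return "".join(_NON_STOP_CODONS[i] for i in idx)


def _random_nt(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def _make_v(rng: np.random.Generator) -> str:
    cys = "TGT" if rng.integers(0, 2) else "TGC"
    pre = _random_codons(rng, V_ANCHOR // 3)
    post = _random_codons(rng, (V_LENGTH - V_ANCHOR - 3) // 3)
    return pre + cys + post


def _make_j(rng: np.random.Generator) -> str:
    head = _random_nt(rng, J_ANCHOR)
    anchor = "TGG" if rng.integers(0, 2) else ("TTT" if rng.integers(0, 2) else "TTC")
    g1 = "GG" + "ACGT"[rng.integers(0, 4)]
    x = _NON_STOP_CODONS[rng.integers(0, len(_NON_STOP_CODONS))]
    g2 = "GG" + "ACGT"[rng.integers(0, 4)]
    tail = _random_codons(rng, (J_LENGTH - J_ANCHOR - 12) // 3)
    return head + anchor + g1 + x + g2 + tail


def build_default_germline(
    n_ighv: int = 20,
    n_igkv: int = 15,
    seed: int = 0,
    n_ighd: int = 10,
    n_ighj: int = 4,
) -> GermlineSet:
    """Build the default down-scaled murine germline set.

    Defaults: 20 Igh-V, 10 Igh-D, 4 Igh-J; 15 Igk-V, 5 Igk-J (4 functional,
    Igkj3 flagged pseudogene); the Igl locus exactly as the two-cassette
    architecture (3 V, 3 J-C units). Deterministic for a fixed ``seed``.
    """
    if n_ighv < 2 or n_igkv < 2:
        raise ValueError("n_ighv and n_igkv must each be >= 2")
    rng = np.random.default_rng(seed)
    gs = GermlineSet()

    for i in range(1, n_ighv + 1):
        gs.add(
            GeneSegment(
                f"Ighv{i}-1", Locus.IGH, SegmentClass.V, _make_v(rng),
                anchor_offset=V_ANCHOR,
            )
        )
    for i in range(1, n_ighd + 1):
        gs.add(
            GeneSegment(
                f"Ighd{i}", Locus.IGH, SegmentClass.D, _random_nt(rng, D_LENGTH)
            )
        )
    for i in range(1, n_ighj + 1):
        gs.add(
            GeneSegment(
                f"Ighj{i}", Locus.IGH, SegmentClass.J, _make_j(rng),
                anchor_offset=J_ANCHOR,
            )
        )

    for i in range(1, n_igkv + 1):
        gs.add(
            GeneSegment(
                f"Igkv{i}", Locus.IGK, SegmentClass.V, _make_v(rng),
                anchor_offset=V_ANCHOR,
            )
        )
    for i in range(1, 6):
        gs.add(
            GeneSegment(
                f"Igkj{i}", Locus.IGK, SegmentClass.J, _make_j(rng),
                anchor_offset=J_ANCHOR, is_functional=(i != 3),
            )
        )
    gs.add(
        GeneSegment("Igkc", Locus.IGK, SegmentClass.C, _random_codons(rng, C_LENGTH // 3))
    )

    for cas, (vs, js) in IGL_CASSETTES.items():
        for v in vs:
            gs.add(
                GeneSegment(
                    v, Locus.IGL, SegmentClass.V, _make_v(rng),
                    cassette=cas, anchor_offset=V_ANCHOR,
                )
            )
        for j in js:
            gs.add(
                GeneSegment(
                    j, Locus.IGL, SegmentClass.J, _make_j(rng),
                    cassette=cas, anchor_offset=J_ANCHOR,
                )
            )
    for i in range(1, 4):
        gs.add(
            GeneSegment(
                f"Iglc{i}", Locus.IGL, SegmentClass.C,
                _random_codons(rng, C_LENGTH // 3),
                cassette=1 if i == 2 else 2,
            )
        )

    gs.validate()
    return gs


# ---------------------------------------------------------------------------
# FASTA serialization
# ---------------------------------------------------------------------------
# Header grammar (pipe-delimited description):
#   >Iglv1|IGL|V|cassette=2|anchor=141|frame=0
# optional fields: cassette=<int>, anchor=<int>, frame=<int>, pseudo=1


def write_germline_fasta(gs: GermlineSet, path: str | Path) -> None:
    records = []
    for seg in gs.segments.values():
        parts = [seg.name, seg.locus.value, seg.segment_class.value]
        if seg.cassette is not None:
            parts.append(f"cassette={seg.cassette}")
        if seg.anchor_offset is not None:
            parts.append(f"anchor={seg.anchor_offset}")
        parts.append(f"frame={seg.reading_frame}")
        if not seg.is_functional:
            parts.append("pseudo=1")
        records.append(
            SeqRecord(Seq(seg.sequence), id="|".join(parts), description="")
        )
    SeqIO.write(records, str(path), "fasta")


def read_germline_fasta(path: str | Path) -> GermlineSet:
    gs = GermlineSet()
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.id.split("|")
        if len(parts) < 3:
            raise GermlineFormatError(
                f"record {rec.id!r}: header needs name|locus|class"
            )
        name, locus_s, cls_s, *rest = parts
        try:
            locus = Locus(locus_s)
            cls = SegmentClass(cls_s)
        except ValueError as e:
            raise GermlineFormatError(f"record {name!r}: {e}") from e
        kv: dict[str, str] = {}
        for item in rest:
            if "=" not in item:
                raise GermlineFormatError(
                    f"record {name!r}: malformed field {item!r}"
                )
            k, v = item.split("=", 1)
            kv[k] = v
        if cls in (SegmentClass.V, SegmentClass.J) and "anchor" not in kv:
            raise GermlineFormatError(
                f"record {name!r}: {cls.value} segment missing anchor field"
            )
        try:
            seg = GeneSegment(
                name=name,
                locus=locus,
                segment_class=cls,
                sequence=str(rec.seq).upper(),
                cassette=int(kv["cassette"]) if "cassette" in kv else None,
                anchor_offset=int(kv["anchor"]) if "anchor" in kv else None,
                reading_frame=int(kv.get("frame", 0)),
                is_functional=kv.get("pseudo", "0") != "1",
            )
        except GermlineError as e:
            raise GermlineFormatError(f"record {name!r}: {e}") from e
        gs.add(seg)
    if not gs.segments:
        raise GermlineFormatError(f"{path}: no germline records found")
    return gs
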