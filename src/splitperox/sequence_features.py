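"""Sequence-level comparison of the peroxidases and their split variants.

Covers N-glycosylation sequon scanning, construction of engineered
variants (point substitutions plus an optional split position), Hamming
distance, and global pairwise sequence identity.

The sequon rule used throughout is Asn-X-Thr/Ser where X is any residue
other than proline or aspartate.  The Asp exclusion is deliberate: it is
the rule used to assign the glycosylation sites of HRP (9 sites) and of
its split variant sHRP (8 sites, N255D having removed one), and is
stricter than the common Pro-only exclusion.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

from Bio import Align
from Bio.Align import substitution_matrices

__all__ = [
    "SequonHit",
    "Substitution",
    "VariantSpec",
    "IdentityResult",
    "scan_sequons",
    "apply_variant",
    "hamming",
    "pairwise_identity",
    "global_alignment",
    "load_reference_sequence",
    "load_variant_spec",
]

_SEQUON_X_EXCLUDED = {"P", "D"}
_AA = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class SequonHit:
    """A potential N-glycosylation site: Asn residue number + its triplet."""

    asn_pos: int
    triplet: str

    def __post_init__(self) -> None:
        assert self.triplet[0] == "N"
        assert self.triplet[2] in {"S", "T"}
        assert self.triplet[1] not in _SEQUON_X_EXCLUDED


@dataclass(frozen=True)
class Substitution:
    wt_aa: str
    position: int
    new_aa: str

    @classmethod
    def parse(cls, text: str) -> "Substitution":
        """Parse mutation shorthand such as ``T21I``."""
        m = re.fullmatch(r"([A-Z])(\d+)([A-Z])", text.strip())
        if not m:
            raise ValueError(f"cannot parse substitution {text!r}")
        return cls(m.group(1), int(m.group(2)), m.group(3))

    def __str__(self) -> str:
        return f"{self.wt_aa}{self.position}{self.new_aa}"


@dataclass
class VariantSpec:
    """Point substitutions plus an optional split position.

    ``split_after`` means the chain is cut between residues
    ``split_after`` and ``split_after + 1``.
    """

    substitutions: list[Substitution] = field(default_factory=list)
    split_after: int | None = None
    name: str = ""

    def __post_init__(self) -> None:
        positions = [s.position for s in self.substitutions]
        if len(set(positions)) != len(positions):
            raise ValueError("substitution positions must be unique")
        for s in self.substitutions:
            if s.wt_aa not in _AA or s.new_aa not in _AA:
                raise ValueError(f"non-standard residue code in {s}")

    @classmethod
    def from_strings(
        cls, mutations: Sequence[str], split_after: int | None = None, name: str = ""
    ) -> "VariantSpec":
        return cls([Substitution.parse(m) for m in mutations], split_after, name)

    @classmethod
    def from_json(cls, path: str | Path) -> "VariantSpec":
        payload = json.loads(Path(path).read_text())
        return cls.from_strings(
            payload["mutations"],
            payload.get("split_after"),
            payload.get("name", Path(path).stem),
        )

    def inverse(self) -> "VariantSpec":
        return VariantSpec(
            [Substitution(s.new_aa, s.position, s.wt_aa) for s in self.substitutions],
            self.split_after,
            f"{self.name}-inverse" if self.name else "",
        )


@dataclass(frozen=True)
class IdentityResult:
    percent_identity: float
    aligned_columns: int
    identities: int
    gap_columns: int


def scan_sequons(
    sequence: str, numbering: Sequence[int] | None = None
) -> list[SequonHit]:
    """Find Asn-X-Ser/Thr sequons (X not Pro/Asp) in an uppercase sequence.

    ``numbering`` maps string position to residue number (defaults to
    1-based positions).  Overlapping hits are allowed; windows truncated
    at the C-terminus are never hits.
    """
    if numbering is None:
        numbering = list(range(1, len(sequence) + 1))
    hits: list[SequonHit] = []
    for i in range(len(sequence) - 2):
        if (
            sequence[i] == "N"
            and sequence[i + 1] not in _SEQUON_X_EXCLUDED
            and sequence[i + 2] in {"S", "T"}
        ):
            hits.append(SequonHit(asn_pos=int(numbering[i]), triplet=sequence[i : i + 3]))
    return hits


def apply_variant(
    sequence: str, spec: VariantSpec
) -> tuple[str, tuple[str, str] | None]:
    """Apply point substitutions; optionally also return the split fragments.

    Each substitution is checked against the wild-type residue it claims
    to replace — a mismatch raises immediately, which guards against
    numbering-offset mistakes.  Returns ``(variant, fragments)`` where
    ``fragments`` is the (N-fragment, C-fragment) pair when
    ``split_after`` is set, else ``None``.  Sequence-level analyses of a
    reconstituted split enzyme use the full-length variant.
    """
    chars = list(sequence)
    for sub in spec.substitutions:
        i = sub.position - 1
        if i < 0 or i >= len(chars):
            raise IndexError(f"substitution {sub} outside sequence of length {len(chars)}")
        if chars[i] != sub.wt_aa:
            raise ValueError(
                f"wild-type mismatch at position {sub.position}: "
                f"expected {sub.wt_aa}, found {chars[i]}"
            )
        chars[i] = sub.new_aa
    variant = "".join(chars)
    fragments = None
    if spec.split_after is not None:
        if not 1 <= spec.split_after < len(variant):
            raise ValueError(f"split position {spec.split_after} outside sequence")
        fragments = (variant[: spec.split_after], variant[spec.split_after :])
    return variant, fragments


def hamming(seq_a: str, seq_b: str) -> int:
    """Number of differing positions between two equal-length sequences."""
    if len(seq_a) != len(seq_b):
        raise ValueError(f"length mismatch: {len(seq_a)} vs {len(seq_b)}")
    return sum(a != b for a, b in zip(seq_a, seq_b))


def _make_aligner(gap_open: float, gap_extend: float, matrix: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -abs(gap_open)
    aligner.extend_gap_score = -abs(gap_extend)
    aligner.mode = "global"
    return aligner


def global_alignment(
    seq_a: str,
    seq_b: str,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
    matrix: str = "BLOSUM62",
) -> tuple[str, str, float]:
    """Global alignment with affine gaps; returns the two gapped strings + score."""
    aligner = _make_aligner(gap_open, gap_extend, matrix)
    aln = aligner.align(seq_a, seq_b)[0]
    return str(aln[0]), str(aln[1]), float(aln.score)


def pairwise_identity(
    seq_a: str,
    seq_b: str,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
    matrix: str = "BLOSUM62",
) -> IdentityResult:
    """Percent identity from a global alignment.

    Identity is counted over aligned columns excluding terminal
    overhangs (leading/trailing gap runs in either sequence); internal
    gap columns stay in the denominator.  Defaults: BLOSUM62, gap open
    10, extend 0.5.
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be nonempty")
    a, b, _ = global_alignment(seq_a, seq_b, gap_open, gap_extend, matrix)
    start = max(len(a) - len(a.lstrip("-")), len(b) - len(b.lstrip("-")))
    end = len(a) - max(len(a) - len(a.rstrip("-")), len(b) - len(b.rstrip("-")))
    a_core, b_core = a[start:end], b[start:end]
    identities = sum(x == y and x != "-" for x, y in zip(a_core, b_core))
    gap_columns = sum(x == "-" or y == "-" for x, y in zip(a_core, b_core))
    aligned_columns = end - start
    return IdentityResult(
        percent_identity=100.0 * identities / aligned_columns,
        aligned_columns=aligned_columns,
        identities=identities,
        gap_columns=gap_columns,
    )


# ---------------------------------------------------------------------------
# Bundled reference data
# ---------------------------------------------------------------------------

_DATA_FILES = {
    "HRP": "hrp_1h5a.fasta",
    "APX": "apx_1oag.fasta",
}
_VARIANT_FILES = {
    "sHRP": "shrp_variant.json",
    "sAPEX2": "sapex2_variant.json",
}


def load_reference_sequence(system: str) -> tuple[str, str]:
    """Bundled reference sequence for ``'HRP'`` (1H5A) or ``'APX'`` (1OAG).

    Returns (identifier, sequence); residue numbering is 1-based and
    matches the crystal-structure numbering used for all site reports
    (His170 proximal in HRP, His163 in APX, etc.).
    """
    try:
        fname = _DATA_FILES[system.upper()]
    except KeyError:
        raise KeyError(f"unknown system {system!r}; expected one of {sorted(_DATA_FILES)}")
    ref = resources.files("splitperox.data").joinpath(fname)
    with resources.as_file(ref) as path:
        from .structure_io import read_fasta

        return read_fasta(path)


def load_variant_spec(name: str) -> VariantSpec:
    """Bundled engineered-variant spec for ``'sHRP'`` or ``'sAPEX2'``."""
    key = {"SHRP": "sHRP", "SAPEX2": "sAPEX2"}.get(name.upper())
    if key is None:
        raise KeyError(f"unknown variant {name!r}; expected sHRP or sAPEX2")
    ref = resources.files("splitperox.data").joinpath(_VARIANT_FILES[key])
    with resources.as_file(ref) as path:
        return VariantSpec.from_json(path)
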