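"""Kabat-numbered antibody VH sequences, point mutations and CDR annotation.

Kabat numbering aligns variable-length antibody loops by attaching lowercase
insertion letters to a fixed residue number (82b, 100d, ...).  Mutations are
written in the usual ``<from><position><to>`` shorthand, e.g. ``E45K`` or
``G82bS``, and a variant is defined by a parent plus such a mutation list.

Besides the numbering itself this module annotates CDR regions -- the three
canonical hypervariable loops plus the non-canonical "CDR4" loop at Kabat
71-78 that sits next to them in VH domains -- and scans for N-linked
glycosylation sequons (N-X-S/T with X != P), which matter because a
D->N mutation in a eukaryotic display host can silently add a glycan.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from functools import total_ordering
from pathlib import Path
from typing import Iterable, Mapping, Sequence

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

_POSITION_RE = re.compile(r"^(\d+)([a-z]?)$")
_MUTATION_RE = re.compile(r"^([A-Z])(\d+[a-z]?)([A-Z])$")


class KabatParseError(ValueError):
    """Raised for malformed Kabat positions or mutation strings."""


class MutationError(ValueError):
    """Raised when a mutation cannot be applied to a sequence."""


@total_ordering
@dataclass(frozen=True)
class KabatPosition:
    """A Kabat residue number with an optional insertion letter.

    The empty insertion code sorts before 'a', so 82 < 82a < 82b < 83.
    """

    number: int
    insertion: str = ""

    def __post_init__(self) -> None:
        if self.number <= 0:
            raise KabatParseError(f"Kabat number must be positive, got {self.number}")
        if self.insertion and (len(self.insertion) != 1 or not self.insertion.islower()):
            raise KabatParseError(
                f"insertion code must be one lowercase letter, got {self.insertion!r}"
            )

    def _key(self) -> tuple[int, str]:
        # "" < "a" < ... < "z" already holds for str comparison
        return (self.number, self.insertion)

    def __lt__(self, other: "KabatPosition") -> bool:
        if not isinstance(other, KabatPosition):
            return NotImplemented
        return self._key() < other._key()

    def __str__(self) -> str:
        return f"{self.number}{self.insertion}"


def parse_kabat_position(text: str) -> KabatPosition:
    """Parse ``"82b"`` -> KabatPosition(82, 'b'); round-trips through str()."""
    m = _POSITION_RE.match(text)
    if not m:
        raise KabatParseError(f"not a valid Kabat position: {text!r}")
    return KabatPosition(int(m.group(1)), m.group(2))


@dataclass(frozen=True)
class Mutation:
    """A point mutation ``from_aa`` -> ``to_aa`` at a Kabat position."""

    from_aa: str
    position: KabatPosition
    to_aa: str

    def __post_init__(self) -> None:
        for aa in (self.from_aa, self.to_aa):
            if aa not in AMINO_ACIDS:
                raise KabatParseError(f"not an amino acid: {aa!r}")
        if self.from_aa == self.to_aa:
            raise KabatParseError(
                f"mutation {self.from_aa}{self.position}{self.to_aa} is a no-op"
            )

    def reverse(self) -> "Mutation":
        return Mutation(self.to_aa, self.position, self.from_aa)

    def __str__(self) -> str:
        return f"{self.from_aa}{self.position}{self.to_aa}"


def parse_mutation(text: str) -> Mutation:
    """Parse ``"G82bS"`` -> Mutation('G', 82b, 'S'); str() round-trips."""
    m = _MUTATION_RE.match(text)
    if not m:
        raise KabatParseError(f"not a valid mutation string: {text!r}")
    return Mutation(m.group(1), parse_kabat_position(m.group(2)), m.group(3))


@dataclass(frozen=True)
class VhVariant:
    """A Kabat-numbered VH sequence, optionally derived from a parent."""

    name: str
    residues: tuple[tuple[KabatPosition, str], ...]
    parent: str | None = None
    mutations_from_parent: tuple[Mutation, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", tuple(tuple(r) for r in self.residues))
        object.__setattr__(
            self, "mutations_from_parent", tuple(self.mutations_from_parent)
        )
        positions = [p for p, _ in self.residues]
        for a, b in zip(positions, positions[1:]):
            if not a < b:
                raise ValueError(f"positions not strictly increasing: {a} !< {b}")

    @property
    def positions(self) -> tuple[KabatPosition, ...]:
        return tuple(p for p, _ in self.residues)

    @property
    def sequence(self) -> str:
        """Linear residue string, numbering gaps ignored."""
        return "".join(aa for _, aa in self.residues)

    def residue_at(self, position: KabatPosition) -> str:
        for p, aa in self.residues:
            if p == position:
                return aa
        raise KeyError(f"position {position} not in {self.name}")


def apply_mutations(
    variant: VhVariant,
    muts: Iterable[Mutation],
    name: str | None = None,
) -> VhVariant:
    """Apply point mutations, checking the expected source residue at each site."""
    muts = tuple(muts)
    index = {p: i for i, (p, _) in enumerate(variant.residues)}
    residues = list(variant.residues)
    for m in muts:
        if m.position not in index:
            raise MutationError(f"{variant.name}: position {m.position} absent")
        pos, found = residues[index[m.position]]
        if found != m.from_aa:
            raise MutationError(
                f"{variant.name} at {m.position}: expected {m.from_aa}, found {found}"
            )
        residues[index[m.position]] = (pos, m.to_aa)
    return VhVariant(
        name=name or f"{variant.name}+{'_'.join(map(str, muts))}",
        residues=tuple(residues),
        parent=variant.name,
        mutations_from_parent=muts,
    )


@dataclass(frozen=True)
class SequonHit:
    """An N-linked glycosylation sequon (N-X-S/T, X != P) anchored at the Asn."""

    position: KabatPosition
    triplet: str

    def __post_init__(self) -> None:
        t = self.triplet
        if not (len(t) == 3 and t[0] == "N" and t[1] != "P" and t[2] in "ST"):
            raise ValueError(f"not a sequon triplet: {t!r}")


def find_sequons(variant: VhVariant) -> list[SequonHit]:
    """Scan the linear sequence for N-X-S/T sequons (X != P), in position order.

    The scan is on consecutive residues in linear order; Kabat numbering gaps are
    ignored because glycosylation recognises the local peptide, not the numbering.
    """
    res = variant.residues
    hits = []
    for i in range(len(res) - 2):
        triplet = res[i][1] + res[i + 1][1] + res[i + 2][1]
        if triplet[0] == "N" and triplet[1] != "P" and triplet[2] in "ST":
            hits.append(SequonHit(position=res[i][0], triplet=triplet))
    return hits


# Standard Kabat heavy-chain CDR bounds plus the non-canonical CDR4 loop.
# CDR1-3 bounds are the standard Kabat definitions, not values from any single
# study; CDR4 = 71-78 is specific to autonomous VH domains.
DEFAULT_CDR_RANGES: dict[str, tuple[str, str]] = {
    "CDR1": ("31", "35"),
    "CDR2": ("50", "65"),
    "CDR3": ("95", "102"),
    "CDR4": ("71", "78"),
}

FRAMEWORK = "framework"


@dataclass(frozen=True)
class CdrAnnotation:
    """Inclusive Kabat ranges for CDR1-4; everything else is framework.

    An inserted position (e.g. 100d) belongs to the region of its parent
    number, so the CDR3 range 95-102 covers 100a-100i.
    """

    ranges: Mapping[str, tuple[KabatPosition, KabatPosition]]

    def __post_init__(self) -> None:
        items = sorted(self.ranges.items(), key=lambda kv: kv[1][0])
        for (na, (sa, ea)), (nb, (sb, eb)) in zip(items, items[1:]):
            if not ea < sb:
                raise ValueError(f"CDR ranges overlap: {na} and {nb}")
        for name, (s, e) in self.ranges.items():
            if e < s:
                raise ValueError(f"empty range for {name}: {s}..{e}")

    @classmethod
    def default(cls) -> "CdrAnnotation":
        return cls.from_strings(DEFAULT_CDR_RANGES)

    @classmethod
    def from_strings(cls, ranges: Mapping[str, tuple[str, str]]) -> "CdrAnnotation":
        return cls(
            {
                name: (parse_kabat_position(s), parse_kabat_position(e))
                for name, (s, e) in ranges.items()
            }
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "CdrAnnotation":
        with open(path) as fh:
            return cls.from_strings({k: tuple(v) for k, v in json.load(fh).items()})

    def region_of(self, position: KabatPosition) -> str:
        # Inserted positions inherit their parent number's region membership.
        base = KabatPosition(position.number)
        for name, (start, end) in self.ranges.items():
            if start <= base and base.number <= end.number:
                return name
        return FRAMEWORK


def annotate_regions(
    variant: VhVariant, scheme: CdrAnnotation | None = None
) -> dict[KabatPosition, str]:
    """Map every position of the variant to CDR1..CDR4 or framework."""
    scheme = scheme or CdrAnnotation.default()
    return {p: scheme.region_of(p) for p, _ in variant.residues}


# ---------------------------------------------------------------------------
# Variant file I/O
# ---------------------------------------------------------------------------

def lineage_from_dict(spec: Mapping) -> dict[str, VhVariant]:
    """Materialise a lineage file: a root sequence plus mutation-list variants.

    Schema::

        {"root": {"name": "WT", "residues": [["1", "E"], ...]},
         "variants": [{"name": "P1", "parent": "WT",
                       "mutations": ["L11P", "E45K", ...]}, ...]}

    Variants may chain (parent may itself be a derived variant); they are
    resolved in file order.
    """
    root = spec["root"]
    wt = VhVariant(
        name=root["name"],
        residues=tuple(
            (parse_kabat_position(p), aa) for p, aa in root["residues"]
        ),
    )
    out = {wt.name: wt}
    for v in spec.get("variants", []):
        parent = out[v["parent"]]
        muts = tuple(parse_mutation(m) for m in v["mutations"])
        out[v["name"]] = apply_mutations(parent, muts, name=v["name"])
    return out


def load_lineage(path: str | Path) -> dict[str, VhVariant]:
    with open(path) as fh:
        return lineage_from_dict(json.load(fh))


def lineage_to_dict(variants: Sequence[VhVariant]) -> dict:
    root = next(v for v in variants if v.parent is None)
    return {
        "root": {
            "name": root.name,
            "residues": [[str(p), aa] for p, aa in root.residues],
        },
        "variants": [
            {
                "name": v.name,
                "parent": v.parent,
                "mutations": [str(m) for m in v.mutations_from_parent],
            }
            for v in variants
            if v.parent is not None
        ],
    }


def write_fasta(variant: VhVariant, fasta_path: str | Path, map_path: str | Path | None = None) -> None:
    """Write the linear sequence as FASTA with a position->residue TSV sidecar."""
    with open(fasta_path, "w") as fh:
        fh.write(f">{variant.name}\n")
        seq = variant.sequence
        for i in range(0, len(seq), 60):
            fh.write(seq[i : i + 60] + "\n")
    if map_path is not None:
        with open(map_path, "w") as fh:
            fh.write("kabat_position\tresidue\n")
            for p, aa in variant.residues:
                fh.write(f"{p}\t{aa}\n")
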