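"""Genome data model, UniMoG-style file I/O and marker-census arithmetic.

A genome is a set of chromosomes; each chromosome is an ordered sequence of
oriented marker occurrences and is either linear or circular.  Markers are
opaque string tokens (gene or segment identifiers); an occurrence carries an
orientation (+1 forward, -1 reverse).  Circular chromosomes are stored in a
canonical form (lexicographically smallest rotation of the smaller of the two
reading directions) so that genome equality is well defined.

The census of a genome pair collects the per-marker multiplicities
Phi_A, Phi_B, their difference DeltaPhi, the common-marker set G, the matched
occurrence count n* = sum_{m in G} min(Phi_A, Phi_B), the linear chromosome
counts kappa_A / kappa_B, and the capping quantities p* = max(kappa_A, kappa_B)
and a* = |kappa_A - kappa_B|.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

__all__ = [
    "Chromosome",
    "Genome",
    "MarkerCensus",
    "GenomeFormatError",
    "parse_genomes",
    "write_genomes",
    "census",
    "write_distance_matrix",
]

#: characters that may not appear inside a marker token
RESERVED = set(">|()-#")

LINEAR_END = "|"
CIRCULAR_END = ")"


class GenomeFormatError(ValueError):
    """Raised for malformed genome files or invalid marker tokens."""


def _check_token(token: str) -> str:
    if not token:
        raise GenomeFormatError("empty marker token")
    if any(ch in RESERVED for ch in token):
        raise GenomeFormatError(f"marker token {token!r} contains a reserved character")
    return token


@dataclass(frozen=True)
class Chromosome:
    """An ordered sequence of oriented marker occurrences.

    ``markers`` holds ``(marker, sign)`` pairs with sign +1 (forward) or -1
    (reverse).  Circular chromosomes are canonicalized on construction.
    """

    markers: tuple[tuple[str, int], ...]
    circular: bool = False

    def __post_init__(self) -> None:
        if not self.markers:
            raise GenomeFormatError("empty chromosome")
        for m, s in self.markers:
            _check_token(m)
            if s not in (1, -1):
                raise GenomeFormatError(f"invalid sign {s!r} for marker {m!r}")
        if self.circular:
            object.__setattr__(self, "markers", _canonical_rotation(self.markers))

    def __len__(self) -> int:
        return len(self.markers)

    def reversed(self) -> "Chromosome":
        return Chromosome(_reverse_seq(self.markers), self.circular)

    def __str__(self) -> str:
        body = " ".join(("-" if s < 0 else "") + m for m, s in self.markers)
        return f"{body} {CIRCULAR_END if self.circular else LINEAR_END}"


def _reverse_seq(seq: Sequence[tuple[str, int]]) -> tuple[tuple[str, int], ...]:
    return tuple((m, -s) for m, s in reversed(seq))


def _canonical_rotation(seq: Sequence[tuple[str, int]]) -> tuple[tuple[str, int], ...]:
    """Smallest rotation of the smaller of the two reading directions."""
    candidates = []
    for direction in (tuple(seq), _reverse_seq(seq)):
        n = len(direction)
        for i in range(n):
            candidates.append(direction[i:] + direction[:i])
    return min(candidates)


@dataclass(frozen=True)
class Genome:
    """A named set of chromosomes."""

    name: str
    chromosomes: tuple[Chromosome, ...]

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise GenomeFormatError(f"genome {self.name!r} has no chromosomes")
        object.__setattr__(self, "chromosomes", tuple(self.chromosomes))

    @property
    def n_linear(self) -> int:
        """kappa: the number of linear chromosomes."""
        return sum(1 for c in self.chromosomes if not c.circular)

    @property
    def n_occurrences(self) -> int:
        return sum(len(c) for c in self.chromosomes)

    def marker_counts(self) -> Counter:
        return Counter(m for c in self.chromosomes for m, _ in c.markers)

    def occurrences(self) -> Iterator[tuple[int, int, str, int, int]]:
        """Yield (chromosome index, position, marker, sign, occurrence index).

        The occurrence index enumerates the occurrences of each marker within
        this genome 1..Phi(m), in chromosome order.
        """
        seen: Counter = Counter()
        for ci, chrom in enumerate(self.chromosomes):
            for pos, (m, s) in enumerate(chrom.markers):
                seen[m] += 1
                yield ci, pos, m, s, seen[m]

    def canonical(self) -> tuple[tuple[tuple[tuple[str, int], ...], bool], ...]:
        """Order-insensitive canonical form, used for genome equality."""
        forms = []
        for c in self.chromosomes:
            if c.circular:
                forms.append((c.markers, True))
            else:
                forms.append((min(c.markers, _reverse_seq(c.markers)), False))
        return tuple(sorted(forms))

    def same_content(self, other: "Genome") -> bool:
        return self.canonical() == other.canonical()

    def __str__(self) -> str:
        lines = [f">{self.name}"]
        lines.extend(str(c) for c in self.chromosomes)
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# parsing / writing


def parse_genomes(text: str | Iterable[str]) -> list[Genome]:
    """Parse genomes from a UniMoG-style dialect.

    ``>`` introduces a genome name; chromosomes are whitespace-separated
    signed tokens terminated by ``|`` (linear) or ``)`` (circular); a ``-``
    prefix marks reverse orientation; ``#`` starts a comment line.
    """
    if not isinstance(text, str):
        text = "".join(text)
    genomes: list[Genome] = []
    names: set[str] = set()
    name: str | None = None
    chroms: list[Chromosome] = []
    current: list[tuple[str, int]] = []

    def flush_genome() -> None:
        nonlocal name, chroms
        if name is None:
            return
        if current:
            raise GenomeFormatError(
                f"unterminated chromosome in genome {name!r} (expected '|' or ')')"
            )
        genomes.append(Genome(name, tuple(chroms)))
        name, chroms = None, []

    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith(">"):
            flush_genome()
            name = line[1:].strip()
            if not name:
                raise GenomeFormatError("missing genome name after '>'")
            if name in names:
                raise GenomeFormatError(f"duplicate genome name {name!r}")
            names.add(name)
            continue
        if name is None:
            raise GenomeFormatError(f"chromosome data before any '>' header: {raw!r}")
        for token in line.split():
            if token in (LINEAR_END, CIRCULAR_END):
                if not current:
                    raise GenomeFormatError(f"empty chromosome in genome {name!r}")
                chroms.append(Chromosome(tuple(current), token == CIRCULAR_END))
                current = []
            else:
                sign = 1
                if token.startswith("-"):
                    sign, token = -1, token[1:]
                current.append((_check_token(token), sign))
    flush_genome()
    if current:
        raise GenomeFormatError("unterminated chromosome at end of input")
    return genomes


def write_genomes(genomes: Iterable[Genome]) -> str:
    return "\n".join(str(g) for g in genomes) + "\n"


# ---------------------------------------------------------------------------
# census


@dataclass
class MarkerCensus:
    """Per-marker multiplicities and capping arithmetic for a genome pair."""

    phiA: Counter
    phiB: Counter
    common: frozenset
    exclusive: frozenset
    n_star: int
    kappaA: int
    kappaB: int
    deltaPhi: dict = field(default_factory=dict)

    @property
    def universe(self) -> frozenset:
        return self.common | self.exclusive

    @property
    def p_star(self) -> int:
        return max(self.kappaA, self.kappaB)

    @property
    def a_star(self) -> int:
        return abs(self.kappaA - self.kappaB)

    @property
    def a_star_side(self) -> str:
        """The genome with fewer linear chromosomes ('none' if equal)."""
        if self.kappaA == self.kappaB:
            return "none"
        return "A" if self.kappaA < self.kappaB else "B"

    def duplicate_occurrences(self) -> int:
        """Occurrences of markers that are duplicated in their genome."""
        return sum(v for v in self.phiA.values() if v > 1) + sum(
            v for v in self.phiB.values() if v > 1
        )


def census(A: Genome, B: Genome) -> MarkerCensus:
    phiA = A.marker_counts()
    phiB = B.marker_counts()
    universe = set(phiA) | set(phiB)
    common = frozenset(m for m in universe if phiA[m] > 0 and phiB[m] > 0)
    delta = {m: phiA[m] - phiB[m] for m in universe}
    n_star = sum(min(phiA[m], phiB[m]) for m in common)
    return MarkerCensus(
        phiA=phiA,
        phiB=phiB,
        common=common,
        exclusive=frozenset(universe - common),
        n_star=n_star,
        kappaA=A.n_linear,
        kappaB=B.n_linear,
        deltaPhi=delta,
    )


def is_singular(A: Genome, B: Genome) -> bool:
    """True if every common marker occurs exactly once in each genome."""
    c = census(A, B)
    return all(c.phiA[m] == 1 and c.phiB[m] == 1 for m in c.common)


# ---------------------------------------------------------------------------
# PHYLIP distance matrix


def write_distance_matrix(names: Sequence[str], D) -> str:
    """Render a PHYLIP square distance matrix.

    ``D`` is a symmetric matrix (nested sequence or ndarray) of non-negative
    values with zero diagonal.
    """
    n = len(names)
    rows = [[D[i][j] for j in range(n)] for i in range(n)]
    for i in range(n):
        if rows[i][i] != 0:
            raise ValueError("distance matrix diagonal must be zero")
        for j in range(n):
            if rows[i][j] != rows[j][i]:
                raise ValueError("distance matrix must be symmetric")
    lines = [str(n)]
    width = max(len(nm) for nm in names)
    for nm, row in zip(names, rows):
        cells = " ".join(_fmt_cell(v) for v in row)
        lines.append(f"{nm.ljust(width)}  {cells}")
    return "\n".join(lines) + "\n"


def _fmt_cell(v) -> str:
    f = float(v)
    if f.is_integer():
        return str(int(f))
    return repr(f)
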