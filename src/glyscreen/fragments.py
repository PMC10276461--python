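"""Glycan tree representation and B/Y/internal fragment enumeration.

A glycan is a rooted tree: the root is the reducing-end monosaccharide
carrying the fluorescent tag, edges are glycosidic bonds.  Collision-induced
dissociation cleaves glycosidic bonds; cutting one to seven bonds and
collecting the connected pieces yields every mathematically possible
fragment:

* **Y-ion** — the piece containing the root (and therefore the tag);
* **B-ion** — a tag-free piece severed by exactly one cut;
* **internal ion** — a tag-free piece with two or more cut boundaries.

Fragments are deduplicated by retained node set; the cut count recorded for
a fragment is the minimal number of bond cleavages that can produce it,
which equals the number of tree edges crossing its boundary.

Structure codes
---------------
Glycans are written reducing-end first.  A unit is a registered 3-letter
code optionally followed by a linkage annotation in square brackets and by
parenthesised branches; whatever follows the unit in the same group
continues the chain as its child::

    GlN(Fuc)GlN Man(Man GlN Gal)(Man)

parses to GlcNAc(root) -> {Fuc, GlcNAc -> Man -> {Man->GlcNAc->Gal, Man}}.
Whitespace is ignored.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Dict, FrozenSet, Iterable, Iterator, List, Optional, Sequence, Set, Tuple, Union

import networkx as nx

from .masses import (
    MONOSACCHARIDES,
    FluorescentTag,
    TAG_PROCA,
    composition_residue_mass,
    get_tag,
)

__all__ = [
    "GlycanTopology",
    "Fragment",
    "FragmentSet",
    "parse_structure_code",
    "enumerate_fragments",
    "fragment_neutral_mass",
    "unique_fragment_masses",
    "multi_residue_unique_fragments",
]

MAX_CUTS = 7
#: Decimal places used when comparing fragment masses for uniqueness.
MASS_DECIMALS = 4


@dataclass
class GlycanTopology:
    """Rooted tree of monosaccharides; node 0 is the reducing end."""

    name: str
    codes: Dict[int, str]
    edges: List[Tuple[int, int]]  # (parent, child)
    linkages: Dict[int, Optional[str]] = field(default_factory=dict)
    root: int = 0

    def __post_init__(self) -> None:
        g = nx.DiGraph()
        g.add_nodes_from(self.codes)
        g.add_edges_from(self.edges)
        if g.number_of_nodes() == 0:
            raise ValueError("glycan topology must have at least one node")
        if not nx.is_arborescence(g) and g.number_of_nodes() > 1:
            raise ValueError("glycan topology must be a rooted tree")
        if self.root not in g:
            raise ValueError("root node missing from topology")
        if g.number_of_nodes() > 1 and set(nx.descendants(g, self.root)) != (
            set(g.nodes) - {self.root}
        ):
            raise ValueError("every node must be reachable from the root")
        for code in self.codes.values():
            if code not in MONOSACCHARIDES:
                raise ValueError(f"unknown monosaccharide code {code!r}")
        self._graph = g

    @property
    def graph(self) -> nx.DiGraph:
        return self._graph

    @property
    def n_nodes(self) -> int:
        return len(self.codes)

    def children(self, node: int) -> List[int]:
        return sorted(self._graph.successors(node))

    def composition(self, nodes: Optional[Iterable[int]] = None) -> Counter:
        """Residue composition {code: count} of the whole tree or a subset."""
        which = self.codes if nodes is None else {n: self.codes[n] for n in nodes}
        return Counter(which.values())

    def labeled_mass(self, tag: Union[str, float, FluorescentTag] = TAG_PROCA) -> float:
        return composition_residue_mass(self.composition()) + get_tag(tag).mass


@dataclass(frozen=True)
class Fragment:
    """One connected piece produced by cutting glycosidic bonds."""

    parent: str
    fragment_id: str
    retained: FrozenSet[int]
    ion_class: str  # "Y", "B", or "internal"
    cut_count: int
    contains_tag: bool
    composition: Tuple[Tuple[str, int], ...]  # sorted (code, count)
    neutral_mass: float

    @property
    def n_residues(self) -> int:
        return sum(n for _, n in self.composition)

    @property
    def composition_str(self) -> str:
        return "".join(f"{code}{n}" for code, n in self.composition)


@dataclass
class FragmentSet:
    """All fragments of one parent glycan, indexed by rounded mass."""

    parent: str
    parent_mass: float
    tag: FluorescentTag
    fragments: List[Fragment]

    def __post_init__(self) -> None:
        index: Dict[float, List[str]] = {}
        for frag in self.fragments:
            index.setdefault(round(frag.neutral_mass, MASS_DECIMALS), []).append(
                frag.fragment_id
            )
        self.mass_index = index

    def __len__(self) -> int:
        return len(self.fragments)

    def __iter__(self) -> Iterator[Fragment]:
        return iter(self.fragments)

    def masses(self) -> Set[float]:
        """Distinct fragment masses, rounded to the comparison precision."""
        return set(self.mass_index)


# -- structure-code parsing -------------------------------------------------


def _tokenize(text: str) -> List[Tuple[str, str, int]]:
    """Split a structure code into (kind, value, position) tokens."""
    tokens: List[Tuple[str, str, int]] = []
    i = 0
    while i < len(text):
        ch = text[i]
        if ch.isspace():
            i += 1
        elif ch in "()":
            tokens.append(("paren", ch, i))
            i += 1
        elif ch == "[":
            j = text.find("]", i)
            if j < 0:
                raise ValueError(f"unclosed linkage annotation at position {i}")
            tokens.append(("link", text[i + 1 : j], i))
            i = j + 1
        elif ch.isalpha():
            j = i
            while j < len(text) and text[j].isalpha():
                j += 1
            word = text[i:j]
            if len(word) % 3 != 0:
                raise ValueError(f"unknown monosaccharide code {word!r} at position {i}")
            # adjacent codes may be written without whitespace: split in threes
            for k in range(0, len(word), 3):
                tokens.append(("code", word[k : k + 3], i + k))
            i = j
        else:
            raise ValueError(f"unexpected character {ch!r} at position {i}")
    return tokens


def parse_structure_code(text: str, name: Optional[str] = None) -> GlycanTopology:
    """Parse a reducing-end-first glycan structure code into a topology."""
    if not text or not text.strip():
        raise ValueError("empty structure code")
    tokens = _tokenize(text)
    codes: Dict[int, str] = {}
    linkages: Dict[int, Optional[str]] = {}
    edges: List[Tuple[int, int]] = []
    pos = 0

    def parse_chain() -> int:
        """Parse one chain inside the current group; return its head node."""
        nonlocal pos
        if pos >= len(tokens) or tokens[pos][0] != "code":
            at = tokens[pos][2] if pos < len(tokens) else len(text)
            raise ValueError(f"expected monosaccharide code at position {at}")
        kind, code, at = tokens[pos]
        if code not in MONOSACCHARIDES:
            raise ValueError(f"unknown monosaccharide code {code!r} at position {at}")
        node = len(codes)
        codes[node] = code
        linkages[node] = None
        pos += 1
        if pos < len(tokens) and tokens[pos][0] == "link":
            linkages[node] = tokens[pos][1]
            pos += 1
        # parenthesised branches
        while pos < len(tokens) and tokens[pos] [:2] == ("paren", "("):
            open_at = tokens[pos][2]
            pos += 1
            if pos < len(tokens) and tokens[pos][:2] == ("paren", ")"):
                raise ValueError(f"empty branch at position {open_at}")
            child = parse_chain()
            if pos >= len(tokens) or tokens[pos][:2] != ("paren", ")"):
                raise ValueError(f"unbalanced parenthesis opened at position {open_at}")
            pos += 1
            edges.append((node, child))
        # chain continuation: the remainder of this group hangs off this node
        if pos < len(tokens) and tokens[pos][0] == "code":
            child = parse_chain()
            edges.append((node, child))
        return node

    root = parse_chain()
    if pos < len(tokens):
        raise ValueError(
            f"unexpected {tokens[pos][1]!r} at position {tokens[pos][2]}"
        )
    return GlycanTopology(name or text.strip(), codes, edges, linkages, root=root)


# -- fragment enumeration ---------------------------------------------------


def _connected_subtrees(
    topology: GlycanTopology, top: int, max_boundary: int
) -> Iterator[Tuple[FrozenSet[int], int]]:
    """Yield (node set, boundary edge count) for connected subtrees whose
    node closest to the root is ``top``.  The boundary count excludes the
    edge from ``top`` to its parent."""

    children = topology.children(top)

    def expand(nodes: FrozenSet[int], boundary: int, remaining: Sequence[int]):
        if boundary > max_boundary:
            return
        if not remaining:
            yield nodes, boundary
            return
        child, rest = remaining[0], remaining[1:]
        # exclude the child branch: one more boundary cut
        yield from expand(nodes, boundary + 1, rest)
        # include a connected subtree topped at the child
        for sub_nodes, sub_boundary in _connected_subtrees(
            topology, child, max_boundary - boundary
        ):
            yield from expand(nodes | sub_nodes, boundary + sub_boundary, rest)

    yield from expand(frozenset({top}), 0, children)


def fragment_neutral_mass(
    composition: Union[Counter, Dict[str, int], Fragment],
    tag: Union[str, float, FluorescentTag],
    contains_tag: bool = False,
) -> float:
    """Neutral mass of a fragment.

    Y-ions (``contains_tag``) carry the labeled reducing end, so the tag
    mass — which absorbs the terminal water — is added; B and internal ions
    are bare residue sums.
    """
    if isinstance(composition, Fragment):
        contains_tag = composition.contains_tag
        composition = dict(composition.composition)
    mass = composition_residue_mass(composition)
    if contains_tag:
        mass += get_tag(tag).mass
    return mass


def enumerate_fragments(
    topology: GlycanTopology,
    max_cuts: int = MAX_CUTS,
    tag: Union[str, float, FluorescentTag] = TAG_PROCA,
    cleave_tag_bond: bool = False,
) -> FragmentSet:
    """Enumerate every B-, Y-, and internal-ion fragment of a glycan.

    Equivalent to cutting every subset of 1..``max_cuts`` glycosidic bonds
    and collecting all connected components (excluding the intact parent),
    deduplicated by retained node set with the minimal cut count kept.  The
    tag-glycan bond is not cleaved unless ``cleave_tag_bond`` is set, in
    which case a bare-tag Y0 ion is added.
    """
    if not 1 <= max_cuts <= MAX_CUTS:
        raise ValueError(f"max_cuts must be in 1..{MAX_CUTS}")
    tag = get_tag(tag)
    all_nodes = frozenset(topology.codes)
    fragments: List[Fragment] = []

    def add(nodes: FrozenSet[int], boundary: int, contains_tag: bool) -> None:
        if contains_tag:
            ion_class = "Y"
        elif boundary == 1:
            ion_class = "B"
        else:
            ion_class = "internal"
        comp = topology.composition(nodes)
        composition = tuple(sorted(comp.items()))
        mass = fragment_neutral_mass(dict(composition), tag, contains_tag)
        fragments.append(
            Fragment(
                parent=topology.name,
                fragment_id="",
                retained=nodes,
                ion_class=ion_class,
                cut_count=boundary,
                contains_tag=contains_tag,
                composition=composition,
                neutral_mass=mass,
            )
        )

    for top in sorted(topology.codes):
        at_root = top == topology.root
        budget = max_cuts if at_root else max_cuts - 1
        if budget < 0:
            continue
        for nodes, boundary in _connected_subtrees(topology, top, budget):
            if at_root:
                if nodes == all_nodes:
                    continue  # the intact parent is not a fragment
                add(nodes, boundary, contains_tag=True)
            else:
                add(nodes, boundary + 1, contains_tag=False)

    if cleave_tag_bond:
        # bare-tag Y0 ion: no residues retained, tag only
        fragments.append(
            Fragment(
                parent=topology.name,
                fragment_id="",
                retained=frozenset(),
                ion_class="Y",
                cut_count=1,
                contains_tag=True,
                composition=(),
                neutral_mass=tag.mass,
            )
        )

    fragments.sort(key=lambda f: (f.neutral_mass, f.ion_class, sorted(f.retained)))
    fragments = [
        Fragment(
            parent=f.parent,
            fragment_id=f"{topology.name}~F{i:03d}",
            retained=f.retained,
            ion_class=f.ion_class,
            cut_count=f.cut_count,
            contains_tag=f.contains_tag,
            composition=f.composition,
            neutral_mass=f.neutral_mass,
        )
        for i, f in enumerate(fragments, start=1)
    ]
    return FragmentSet(
        parent=topology.name,
        parent_mass=topology.labeled_mass(tag),
        tag=tag,
        fragments=fragments,
    )


def unique_fragment_masses(
    target: FragmentSet, others: Iterable[FragmentSet]
) -> Set[float]:
    """Fragment masses present in ``target`` and in none of ``others``.

    Masses are compared rounded to four decimals; all sets must be built
    with the same tag for the comparison to be meaningful.
    """
    other_masses: Set[float] = set()
    for fs in others:
        if fs is target:
            return set()
        other_masses |= fs.masses()
    return target.masses() - other_masses


def multi_residue_unique_fragments(fragment_set: FragmentSet) -> FragmentSet:
    """Fragments of 2+ residues whose mass is unique within their own set.

    These are the "qualifying" fragments used as the denominator of the
    percent-identified statistic: single residues and mass-degenerate
    fragments carry no discriminating information.
    """
    counts = Counter(round(f.neutral_mass, MASS_DECIMALS) for f in fragment_set)
    kept = [
        f
        for f in fragment_set
        if f.n_residues >= 2 and counts[round(f.neutral_mass, MASS_DECIMALS)] == 1
    ]
    return FragmentSet(
        parent=fragment_set.parent,
        parent_mass=fragment_set.parent_mass,
        tag=fragment_set.tag,
        fragments=kept,
    )
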