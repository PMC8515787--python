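"""Index-invariant distance-matrix representation and its inverses.

A plain atom–atom distance matrix is translation- and rotation-
invariant but still depends on the (arbitrary) atom input order.  The
index-invariant form removes that dependence: rows are grouped per
element and sorted within each group by distance to a chosen reference
atom; each row's columns are grouped and sorted the same way, but by
distance to the *row* atom.  A column index therefore names a different
physical atom in each row, which is flagged with a prime in the label
notation (e.g. ``O2-H5'``: the distance from the third-closest oxygen
to the reference to that oxygen's sixth-closest hydrogen; ranks are
0-based).

Because the permutations are recorded, the transformation is
reversible: ``unsort`` recovers the symmetric matrix (up to an atom
relabeling), and a symmetric distance matrix can be back-mapped to 3D
coordinates (up to a rigid motion) by classical multidimensional
scaling, i.e. eigendecomposition of the double-centred squared-distance
Gram matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .trajio import Frame

__all__ = [
    "DistanceMatrix",
    "InvariantMatrix",
    "FeatureLabel",
    "ATOMIC_NUMBERS",
    "distance_matrix",
    "select_reference_atom",
    "default_group_order",
    "index_invariant_matrix",
    "feature_labels",
    "flatten",
    "unsort",
    "backmap_coordinates",
    "place_dummy_atoms",
]

log = logging.getLogger(__name__)

ATOMIC_NUMBERS = {
    "H": 1, "He": 2, "Li": 3, "Be": 4, "B": 5, "C": 6, "N": 7, "O": 8,
    "F": 9, "Ne": 10, "Na": 11, "Mg": 12, "Al": 13, "Si": 14, "P": 15,
    "S": 16, "Cl": 17, "Ar": 18, "K": 19, "Ca": 20, "X": 0,
}


@dataclass
class DistanceMatrix:
    """Symmetric pairwise-distance matrix in original atom order (Å)."""

    values: np.ndarray  # (M, M)
    elements: tuple[str, ...]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.elements = tuple(self.elements)
        m = len(self.elements)
        if self.values.shape != (m, m):
            raise ValueError("values must be square and match elements")


@dataclass
class FeatureLabel:
    """Rank-based name of one invariant-matrix entry, e.g. ``O2-H5'``."""

    row_element: str
    row_rank: int
    col_element: str
    col_rank: int

    def row_label(self) -> str:
        return f"{self.row_element}{self.row_rank}"

    def col_label(self) -> str:
        return f"{self.col_element}{self.col_rank}'"

    def __str__(self) -> str:
        return f"{self.row_label()}-{self.col_label()}"

    @classmethod
    def parse(cls, text: str) -> "FeatureLabel":
        """Parse the rendered form, e.g. ``O2-H5'`` or ``H9-H11'``."""
        try:
            row, col = text.split("-")
            if not col.endswith("'"):
                raise ValueError
            re_, rr = _split_symbol(row)
            ce, cr = _split_symbol(col[:-1])
        except ValueError:
            raise ValueError(f"cannot parse feature label {text!r}") from None
        return cls(re_, rr, ce, cr)


def _split_symbol(token: str) -> tuple[str, int]:
    alpha = "".join(c for c in token if c.isalpha())
    digits = token[len(alpha):]
    if not alpha or not digits.isdigit():
        raise ValueError(token)
    return alpha, int(digits)


@dataclass
class InvariantMatrix:
    """Element-grouped, distance-sorted matrix plus its permutations.

    ``row_order[i]`` is the original index of the atom behind sorted row
    i; ``col_order[i][j]`` the original index of the atom behind column
    j of sorted row i.  Applying these to the symmetric matrix
    reproduces ``values`` exactly.
    """

    values: np.ndarray  # (M, M)
    row_order: np.ndarray  # (M,) original atom indices
    col_order: np.ndarray  # (M, M) original atom indices, one row each
    ref_atom: int
    element_group_order: tuple[str, ...]
    elements: tuple[str, ...]  # original atom order, for label resolution

    @property
    def n_atoms(self) -> int:
        return self.values.shape[0]


def distance_matrix(frame: Frame) -> DistanceMatrix:
    """Pairwise Euclidean distances between all atoms of a frame."""
    if frame.n_atoms == 1:
        vals = np.zeros((1, 1))
    else:
        vals = squareform(pdist(frame.coords))
    return DistanceMatrix(values=vals, elements=frame.elements)


def select_reference_atom(frame: Frame, rule) -> int:
    """Resolve the reference atom from an element symbol or explicit index.

    An element rule must match exactly one atom; otherwise the caller
    must disambiguate with an explicit index.
    """
    if isinstance(rule, (int, np.integer)):
        idx = int(rule)
        if not 0 <= idx < frame.n_atoms:
            raise ValueError(f"reference index {idx} out of range")
        return idx
    matches = [i for i, el in enumerate(frame.elements) if el == rule]
    if len(matches) != 1:
        raise ValueError(
            f"element rule {rule!r} matches {len(matches)} atoms; "
            "give an explicit atom index instead"
        )
    return matches[0]


def default_group_order(elements: Sequence[str], ref_atom: int) -> tuple[str, ...]:
    """Reference atom's element first, the rest by descending atomic number."""
    ref_el = elements[ref_atom]
    rest = sorted(
        {el for el in elements if el != ref_el},
        key=lambda el: (-ATOMIC_NUMBERS.get(el, -1), el),
    )
    return (ref_el, *rest)


def _grouped_sort(elements: Sequence[str], dist_to_anchor: np.ndarray,
                  group_order: Sequence[str]) -> list[int]:
    """Atom indices grouped by element (in group_order) then ascending
    distance to the anchor; exact ties keep original index order."""
    order: list[int] = []
    for el in group_order:
        members = [i for i, e in enumerate(elements) if e == el]
        members.sort(key=lambda i: dist_to_anchor[i])  # stable: ties by index
        order.extend(members)
    return order


def index_invariant_matrix(
    dmat: DistanceMatrix, ref: int, group_order: Sequence[str] | None = None
) -> InvariantMatrix:
    """Sort a distance matrix into its index-invariant form.

    Self-distances (the zero diagonal) are retained, so each row atom
    appears at rank 0 of its own element group in its own row and the
    flattened vector has length M².
    """
    elements = dmat.elements
    m = len(elements)
    if not 0 <= ref < m:
        raise ValueError(f"reference atom {ref} out of range")
    if group_order is None:
        group_order = default_group_order(elements, ref)
    missing = set(elements) - set(group_order)
    if missing:
        raise ValueError(f"group_order is missing elements {sorted(missing)}")

    row_order = _grouped_sort(elements, dmat.values[ref], group_order)
    col_order = np.empty((m, m), dtype=int)
    values = np.empty((m, m))
    for i, atom in enumerate(row_order):
        cols = _grouped_sort(elements, dmat.values[atom], group_order)
        col_order[i] = cols
        values[i] = dmat.values[atom, cols]
    return InvariantMatrix(
        values=values,
        row_order=np.array(row_order, dtype=int),
        col_order=col_order,
        ref_atom=int(ref),
        element_group_order=tuple(group_order),
        elements=elements,
    )


def _group_layout(elements: Sequence[str], group_order: Sequence[str]):
    """(ordered element, rank) for each sorted position, plus offsets."""
    counts = {el: sum(1 for e in elements if e == el) for el in group_order}
    layout: list[tuple[str, int]] = []
    offsets: dict[str, int] = {}
    for el in group_order:
        offsets[el] = len(layout)
        layout.extend((el, r) for r in range(counts[el]))
    return layout, offsets


def feature_labels(
    elements: Sequence[str], group_order: Sequence[str] | None = None,
    ref_element: str | None = None,
) -> list[list[FeatureLabel]]:
    """The M×M grid of labels aligned with ``InvariantMatrix.values``.

    Because every row's columns follow the same element-group layout,
    the column label at position j is the same (element, rank) pair for
    all rows — but names a different physical atom per row, hence the
    prime.
    """
    if group_order is None:
        if ref_element is None:
            raise ValueError("give group_order or ref_element")
        ref_idx = next(i for i, e in enumerate(elements) if e == ref_element)
        group_order = default_group_order(elements, ref_idx)
    layout, _ = _group_layout(elements, group_order)
    return [
        [FeatureLabel(re_, rr, ce, cr) for (ce, cr) in layout]
        for (re_, rr) in layout
    ]


def flatten(inv: InvariantMatrix) -> tuple[np.ndarray, list[FeatureLabel]]:
    """Row-major feature vector (length M²) with its parallel labels."""
    labels = feature_labels(inv.elements, inv.element_group_order)
    flat_labels = [lab for row in labels for lab in row]
    return inv.values.reshape(-1).copy(), flat_labels


def unsort(inv: InvariantMatrix) -> DistanceMatrix:
    """Reconstruct the symmetric matrix in sorted-row atom order.

    Pure index manipulation — no arithmetic — so the result is exact.
    """
    m = inv.n_atoms
    if sorted(inv.row_order.tolist()) != list(range(m)):
        raise ValueError("row_order is not a permutation")
    pos = np.empty(m, dtype=int)
    pos[inv.row_order] = np.arange(m)
    out = np.empty((m, m))
    for i in range(m):
        cols = inv.col_order[i]
        if sorted(cols.tolist()) != list(range(m)):
            raise ValueError(f"col_order row {i} is not a permutation")
        out[i, pos[cols]] = inv.values[i]
    if not np.array_equal(out, out.T):
        raise ValueError("inconsistent permutations: reconstruction is not symmetric")
    elements = tuple(inv.elements[a] for a in inv.row_order)
    return DistanceMatrix(values=out, elements=elements)


def backmap_coordinates(dmat: DistanceMatrix | np.ndarray, rtol: float = 1e-9) -> np.ndarray:
    """Recover 3D coordinates from a symmetric distance matrix.

    Classical multidimensional scaling: the squared-distance matrix is
    double-centred into a Gram matrix whose top three eigenpairs give
    coordinates ``V sqrt(Λ)``, unique up to translation, rotation and
    reflection.  Inputs that are not embeddable in 3D (more than three
    eigenvalues above ``rtol`` × the largest) are approximated at rank 3
    with a warning; small negative eigenvalues are clamped to zero.
    """
    d = dmat.values if isinstance(dmat, DistanceMatrix) else np.asarray(dmat, dtype=float)
    m = d.shape[0]
    if d.shape != (m, m) or not np.allclose(d, d.T) or not np.allclose(np.diag(d), 0):
        raise ValueError("input must be a symmetric matrix with zero diagonal")
    if m == 1:
        return np.zeros((1, 3))
    d2 = d ** 2
    j = np.eye(m) - np.full((m, m), 1.0 / m)
    gram = -0.5 * j @ d2 @ j
    evals, evecs = np.linalg.eigh(gram)  # ascending
    evals, evecs = evals[::-1], evecs[:, ::-1]
    tol = rtol * max(evals[0], 0.0) if evals[0] > 0 else 0.0
    if m > 4 and np.sum(evals > tol) > 3:
        log.warning(
            "distance matrix is not 3D-embeddable (%d significant eigenvalues); "
            "returning best rank-3 approximation", int(np.sum(evals > tol)),
        )
    top = evals[:3].copy()
    if np.any(top < -tol):
        log.warning("clamping negative Gram eigenvalues %s to zero", top[top < -tol])
    top = np.clip(top, 0.0, None)
    coords = evecs[:, :3] * np.sqrt(top)
    return coords


def resolve_feature_atoms(label: FeatureLabel, inv: InvariantMatrix) -> tuple[int, int]:
    """Original atom indices of the pair an invariant entry refers to."""
    layout, offsets = _group_layout(inv.elements, inv.element_group_order)
    counts = {el: sum(1 for e in inv.elements if e == el) for el in inv.element_group_order}
    for el, rank in ((label.row_element, label.row_rank), (label.col_element, label.col_rank)):
        if el not in counts or rank >= counts[el]:
            raise ValueError(
                f"label {label} not resolvable: no rank-{rank} {el} in this system"
            )
    row_pos = offsets[label.row_element] + label.row_rank
    col_pos = offsets[label.col_element] + label.col_rank
    return int(inv.row_order[row_pos]), int(inv.col_order[row_pos, col_pos])


def place_dummy_atoms(
    frame: Frame, node_features: Sequence[FeatureLabel], inv: InvariantMatrix
) -> Frame:
    """Append marker atoms (element ``X``) at the atoms behind each split.

    Two markers per decision-path node, coincident with the two real
    atoms of the split's pair, so visualization software can highlight
    and measure them.  The original atoms are untouched.
    """
    extra: list[np.ndarray] = []
    for lab in node_features:
        a, b = resolve_feature_atoms(lab, inv)
        extra.append(frame.coords[a])
        extra.append(frame.coords[b])
    if not extra:
        return frame
    coords = np.vstack([frame.coords, np.array(extra)])
    elements = frame.elements + ("X",) * len(extra)
    return Frame(elements=elements, coords=coords, time_index=frame.time_index)
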