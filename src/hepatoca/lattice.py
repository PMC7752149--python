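"""Site graphs for the simulated tissue.

Three geometries are supported:

* a 1D chain of ``n`` hepatocytes representing a sinusoidal cord running
  from the central vein (CV, next to site 0) to a portal triad (PT),
* a 2D hexagonal lobule: concentric rings of hexagonal cells around an
  unmodeled CV, with CV-to-PT length ``nl`` rings and ``3*nl*(nl+1)`` sites,
* a 3D stack of identical hexagonal lobule planes with vertical contacts.

A :class:`Lattice` is immutable.  It stores, per site, the distance from
the CV in cell layers (``layer_of``, 1 = touching the CV), the first-order
(contact) neighbor lists and the second-order (distance-2 shell) neighbor
lists.  Boundary sites simply have shorter lists; the conversion rule
normalises by the actual list length.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = ["Lattice", "build_chain", "build_hex_lobule", "build_hex_stack"]

# axial-coordinate displacement vectors of the six hexagonal contact neighbors
_HEX_DIRS = ((1, 0), (0, 1), (-1, 1), (-1, 0), (0, -1), (1, -1))


def _hex_distance(q: int, r: int) -> int:
    """Hex (cube) distance of axial coordinate (q, r) from the origin."""
    return (abs(q) + abs(r) + abs(q + r)) // 2


def _ring_coords(k: int) -> list[tuple[int, int]]:
    """Axial coordinates of ring ``k`` around the origin, in angular order."""
    coords = []
    q, r = k, 0  # start on the +q axis and walk around
    for d in (2, 3, 4, 5, 0, 1):
        dq, dr = _HEX_DIRS[d]
        for _ in range(k):
            coords.append((q, r))
            q, r = q + dq, r + dr
    return coords


@dataclass(frozen=True)
class Lattice:
    """Immutable site graph.

    Attributes
    ----------
    n_sites : int
        Total number of cell sites ``N`` (the CV itself is not a site).
    geometry : str
        One of ``chain``, ``hex_lobule``, ``hex_stack``.
    nl : int
        CV-to-PT length in cell layers (``N_L``); for a chain, ``nl == n_sites``.
    layer_of : ndarray of int
        Per-site distance from the CV in cell layers (1-based).
    neighbors1, neighbors2 : tuple of tuple of int
        Per-site first-order / second-order neighbor index lists.
    """

    n_sites: int
    geometry: str
    nl: int
    layer_of: np.ndarray
    neighbors1: tuple[tuple[int, ...], ...]
    neighbors2: tuple[tuple[int, ...], ...]
    n_planes: int = 1
    # padded adjacency matrices for the vectorized engine, built lazily
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    # -- padded adjacency ------------------------------------------------
    def _padded(self, lists: tuple[tuple[int, ...], ...]) -> tuple[np.ndarray, np.ndarray]:
        """(N, max_deg) index matrix padded with the sentinel ``n_sites``."""
        counts = np.array([len(v) for v in lists], dtype=np.int64)
        width = max(1, int(counts.max()) if len(counts) else 1)
        idx = np.full((self.n_sites, width), self.n_sites, dtype=np.int64)
        for i, v in enumerate(lists):
            idx[i, : len(v)] = v
        return idx, counts

    def adjacency(self, order: str = "first") -> tuple[np.ndarray, np.ndarray]:
        """Padded neighbor-index matrix and per-site neighbor counts.

        ``order`` is ``"first"`` (contact neighbors) or ``"first_and_second"``
        (union of the two shells, as used by the conversion rule with
        second-order signalling).  Padding entries equal ``n_sites`` and
        must be masked with a sentinel state.
        """
        if order not in self._cache:
            if order == "first":
                lists = self.neighbors1
            elif order == "first_and_second":
                lists = tuple(a + b for a, b in zip(self.neighbors1, self.neighbors2))
            else:
                raise ValueError(f"unknown neighbor order: {order!r}")
            self._cache[order] = self._padded(lists)
        return self._cache[order]

    # -- serialization ---------------------------------------------------
    def to_json(self) -> str:
        """Serialize sites, layers and adjacency to a JSON document."""
        doc = {
            "n_sites": self.n_sites,
            "geometry": self.geometry,
            "nl": self.nl,
            "n_planes": self.n_planes,
            "layer_of": self.layer_of.tolist(),
            "neighbors1": [list(v) for v in self.neighbors1],
            "neighbors2": [list(v) for v in self.neighbors2],
        }
        return json.dumps(doc)

    @classmethod
    def from_json(cls, text: str) -> "Lattice":
        doc = json.loads(text)
        return cls(
            n_sites=doc["n_sites"],
            geometry=doc["geometry"],
            nl=doc["nl"],
            n_planes=doc.get("n_planes", 1),
            layer_of=np.asarray(doc["layer_of"], dtype=np.int64),
            neighbors1=tuple(tuple(v) for v in doc["neighbors1"]),
            neighbors2=tuple(tuple(v) for v in doc["neighbors2"]),
        )


def build_chain(n: int) -> Lattice:
    """1D chain of ``n`` sites; site 0 is adjacent to the CV.

    Site ``i`` sits in layer ``i + 1``; interior sites have two contact
    neighbors and the two end sites one.  The second-order shell is empty
    by convention for chains (the 1D model uses contact neighbors only).
    """
    n = int(n)
    if n < 1:
        raise ValueError(f"chain length must be positive, got {n}")
    nbr1 = tuple(
        tuple(j for j in (i - 1, i + 1) if 0 <= j < n) for i in range(n)
    )
    nbr2 = tuple(() for _ in range(n))
    return Lattice(
        n_sites=n,
        geometry="chain",
        nl=n,
        layer_of=np.arange(1, n + 1, dtype=np.int64),
        neighbors1=nbr1,
        neighbors2=nbr2,
    )


def _hex_lobule_sites(nl: int) -> tuple[list[tuple[int, int]], np.ndarray]:
    """Axial coordinates (ring-major, angular order) and layer indices."""
    coords: list[tuple[int, int]] = []
    layers: list[int] = []
    for k in range(1, nl + 1):
        ring = _ring_coords(k)
        coords.extend(ring)
        layers.extend([k] * len(ring))
    return coords, np.asarray(layers, dtype=np.int64)


def build_hex_lobule(nl: int) -> Lattice:
    """2D hexagonal lobule with CV-to-PT length ``nl`` rings.

    The CV sits at the axial origin and is not itself a site, so
    ``n_sites = 3*nl*(nl+1)`` (ring ``k`` holds ``6k`` sites).  First-order
    neighbors are hex-adjacent sites; second-order neighbors are the sites
    at hexagonal distance exactly 2 (12 for interior sites, fewer at the
    lobule boundary — the shell truncates, it does not wrap).
    """
    nl = int(nl)
    if nl < 1:
        raise ValueError(f"lobule CV-PT length must be positive, got {nl}")
    coords, layers = _hex_lobule_sites(nl)
    index = {c: i for i, c in enumerate(coords)}

    nbr1, nbr2 = [], []
    for q, r in coords:
        first = [
            index[(q + dq, r + dr)]
            for dq, dr in _HEX_DIRS
            if (q + dq, r + dr) in index
        ]
        second = []
        for dq in range(-2, 3):
            for dr in range(-2, 3):
                if _hex_distance(dq, dr) == 2 and (q + dq, r + dr) in index:
                    second.append(index[(q + dq, r + dr)])
        nbr1.append(tuple(first))
        nbr2.append(tuple(sorted(second)))

    return Lattice(
        n_sites=len(coords),
        geometry="hex_lobule",
        nl=nl,
        layer_of=layers,
        neighbors1=tuple(nbr1),
        neighbors2=tuple(nbr2),
    )


def build_hex_stack(nl: int, n_planes: int) -> Lattice:
    """Stack of ``n_planes`` hexagonal lobule planes along the z axis.

    Each site is additionally in contact with the same in-plane position one
    plane above and below (where present), so interior sites of interior
    planes have 8 contact neighbors.  Second-order shells remain in-plane.
    """
    nl, n_planes = int(nl), int(n_planes)
    if nl < 1 or n_planes < 1:
        raise ValueError(
            f"lobule size and plane count must be positive, got nl={nl}, n_planes={n_planes}"
        )
    base = build_hex_lobule(nl)
    per = base.n_sites

    nbr1, nbr2 = [], []
    for p in range(n_planes):
        off = p * per
        for i in range(per):
            first = [off + j for j in base.neighbors1[i]]
            if p > 0:
                first.append(off - per + i)
            if p < n_planes - 1:
                first.append(off + per + i)
            nbr1.append(tuple(first))
            nbr2.append(tuple(off + j for j in base.neighbors2[i]))

    return Lattice(
        n_sites=per * n_planes,
        geometry="hex_stack",
        nl=nl,
        n_planes=n_planes,
        layer_of=np.tile(base.layer_of, n_planes),
        neighbors1=tuple(nbr1),
        neighbors2=tuple(nbr2),
    )
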