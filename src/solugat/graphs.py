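"""Residue-level protein graphs from 3D structures.

A protein of length L is represented by the Euclidean distance matrix between
its Calpha atoms (in angstroms) and, after thresholding at a distance cutoff,
by a binary symmetric adjacency matrix whose nodes are residues in file order.
Self-loops are stored explicitly so that every node's attention neighborhood
includes the node itself.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionException, PDBConstructionWarning
from Bio.SeqUtils import seq1

logger = logging.getLogger(__name__)

DEFAULT_CUTOFF = 10.0  # angstroms
CUTOFF_SWEEP = (6.0, 8.0, 10.0, 12.0)

_STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass
class CalphaTrace:
    """Ordered Calpha trace of one protein.

    ``residues`` holds ``(residue_number, one_letter_code)`` pairs in file
    order (residue numbers are metadata only; internal indexing is 0-based).
    ``coords`` is the L x 3 coordinate matrix in angstroms.
    """

    protein_id: str
    residues: list[tuple[int, str]]
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be an L x 3 matrix")
        if len(self.residues) != self.coords.shape[0]:
            raise ValueError(
                f"residue list ({len(self.residues)}) and coordinate rows "
                f"({self.coords.shape[0]}) disagree"
            )
        if self.coords.shape[0] < 1:
            raise ValueError("trace must contain at least one residue")
        for _, aa in self.residues:
            if aa not in _STANDARD_AA and aa != "X":
                raise ValueError(f"illegal residue code {aa!r}")

    def __len__(self) -> int:
        return self.coords.shape[0]

    @property
    def sequence(self) -> str:
        return "".join(aa for _, aa in self.residues)


@dataclass
class DistanceMap:
    """Symmetric L x L Calpha-Calpha Euclidean distance matrix (angstroms)."""

    protein_id: str
    D: np.ndarray

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=np.float64)
        if self.D.ndim != 2 or self.D.shape[0] != self.D.shape[1]:
            raise ValueError("D must be square")

    def __len__(self) -> int:
        return self.D.shape[0]


@dataclass
class ProteinGraph:
    """Binary residue adjacency at a distance cutoff, self-loops included."""

    protein_id: str
    A: np.ndarray
    cutoff: float

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=np.int8)

    def __len__(self) -> int:
        return self.A.shape[0]

    @property
    def n_edges(self) -> int:
        """Number of undirected non-self edges."""
        return int((self.A.sum() - np.trace(self.A)) // 2)

    def edge_set(self) -> set[tuple[int, int]]:
        """Undirected edges as sorted (i, j) pairs, i < j."""
        ii, jj = np.nonzero(np.triu(self.A, k=1))
        return set(zip(ii.tolist(), jj.tolist()))


def parse_calpha_trace(pdb_text: str, protein_id: str = "protein") -> CalphaTrace:
    """Extract the Calpha trace from PDB text.

    Conventions: first MODEL only; altloc resolved to the highest-occupancy
    conformer (ties keep the first listed); HETATM records are ignored; chains
    are concatenated in file order into one node ordering.  Residues without a
    Calpha atom are skipped with a warning.

    Raises ``ValueError`` if no CA atoms are found or a coordinate field is
    malformed (the error names the offending record).
    """
    parser = PDBParser(PERMISSIVE=False, QUIET=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", PDBConstructionWarning)
            structure = parser.get_structure(protein_id, io.StringIO(pdb_text))
    except (PDBConstructionException, ValueError) as exc:
        raise ValueError(f"malformed PDB record: {exc}") from exc

    models = list(structure)
    if not models:
        raise ValueError("no CA atoms found: structure contains no model")
    model = models[0]

    residues: list[tuple[int, str]] = []
    coords: list[np.ndarray] = []
    for chain in model:
        for residue in chain:
            hetflag, resseq, _ = residue.id
            if hetflag.strip():  # HETATM / water
                continue
            if "CA" not in residue:
                logger.warning(
                    "%s: residue %s %s%d has no CA atom; skipped",
                    protein_id, residue.get_resname(), chain.id, resseq,
                )
                continue
            ca = residue["CA"]  # DisorderedAtom resolves to top occupancy
            aa = seq1(residue.get_resname())
            if aa not in _STANDARD_AA:
                aa = "X"
            residues.append((resseq, aa))
            coords.append(np.asarray(ca.get_coord(), dtype=np.float64))

    if not residues:
        raise ValueError("no CA atoms found in any ATOM record")
    return CalphaTrace(protein_id=protein_id, residues=residues,
                       coords=np.vstack(coords))


def compute_distance_map(trace: CalphaTrace) -> DistanceMap:
    """Pairwise Euclidean Calpha distances in angstroms."""
    if len(trace) == 1:
        D = np.zeros((1, 1))
    else:
        D = squareform(pdist(trace.coords))
    return DistanceMap(protein_id=trace.protein_id, D=D)


def threshold_adjacency(dmap: DistanceMap, cutoff: float = DEFAULT_CUTOFF) -> ProteinGraph:
    """Binarize a distance map: edge iff D[i,j] < cutoff (strict), self-loops set.

    The strict "below" rule means a pair at exactly the cutoff distance does
    not form an edge.
    """
    if cutoff <= 0:
        raise ValueError(f"cutoff must be positive, got {cutoff}")
    A = (dmap.D < cutoff).astype(np.int8)
    np.fill_diagonal(A, 1)
    return ProteinGraph(protein_id=dmap.protein_id, A=A, cutoff=float(cutoff))


def build_graph(pdb_text: str, cutoff: float = DEFAULT_CUTOFF,
                protein_id: str = "protein") -> tuple[CalphaTrace, ProteinGraph]:
    """Parse -> distance map -> thresholded graph in one call."""
    trace = parse_calpha_trace(pdb_text, protein_id=protein_id)
    return trace, threshold_adjacency(compute_distance_map(trace), cutoff)


# ---------------------------------------------------------------------------
# edge-list text format
# ---------------------------------------------------------------------------

def write_edge_list(graph: ProteinGraph, path) -> None:
    """Write a graph as a header plus 0-based ``i j`` pairs (i < j).

    Self-loops are implied by the format and not listed.
    """
    from . import __version__
    with open(path, "w") as fh:
        fh.write(f"#generator=solugat {__version__}\n")
        fh.write(f"#protein_id={graph.protein_id}\n")
        fh.write(f"#cutoff={graph.cutoff:g}\n")
        fh.write(f"#n_nodes={len(graph)}\n")
        for i, j in sorted(graph.edge_set()):
            fh.write(f"{i} {j}\n")


def read_edge_list(path) -> ProteinGraph:
    header: dict[str, str] = {}
    edges: list[tuple[int, int]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, value = line[1:].partition("=")
                header[key] = value
            else:
                i, j = line.split()
                edges.append((int(i), int(j)))
    try:
        n = int(header["n_nodes"])
        cutoff = float(header["cutoff"])
        protein_id = header["protein_id"]
    except KeyError as exc:
        raise ValueError(f"edge-list file missing header field {exc}") from exc
    A = np.eye(n, dtype=np.int8)
    for i, j in edges:
        A[i, j] = A[j, i] = 1
    return ProteinGraph(protein_id=protein_id, A=A, cutoff=cutoff)
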