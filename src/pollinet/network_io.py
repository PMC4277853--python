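"""Read, validate and write bipartite plant-pollinator networks and phylogenies.

The canonical in-memory objects used by every other stage are defined here:
:class:`BipartiteNetwork` (a labeled plants x pollinators weight matrix with
per-plant exotic flags) and :class:`PlantPhylogeny` (a rooted, dated tree over
plant taxa backed by dendropy).

Matrix orientation is fixed: plants are rows, pollinators are columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
import yaml

__all__ = [
    "BipartiteNetwork",
    "PlantPhylogeny",
    "NetworkFormatError",
    "NetworkValidationError",
    "EmptyNetworkError",
    "read_network",
    "write_network",
    "read_phylogeny",
    "drop_unconnected",
]


class NetworkFormatError(ValueError):
    """The on-disk representation cannot be parsed into a network."""


class NetworkValidationError(ValueError):
    """The parsed data violate a network invariant (e.g. negative weight)."""


class EmptyNetworkError(NetworkValidationError):
    """An operation produced or received a network with no plants/pollinators."""


def _normalize_name(name: str) -> str:
    return " ".join(str(name).split()).casefold()


@dataclass(frozen=True)
class BipartiteNetwork:
    """A labeled plant x pollinator interaction matrix.

    Parameters
    ----------
    plant_ids, pollinator_ids
        Unique labels; row/column order of ``weights``.
    weights
        Non-negative (P, A) array of visit counts; values in {0, 1} when
        ``quantitative`` is False.
    quantitative
        True when cell values are visitation counts rather than presence.
    exotic
        Per-plant boolean flags, aligned with ``plant_ids``.
    """

    plant_ids: tuple[str, ...]
    pollinator_ids: tuple[str, ...]
    weights: np.ndarray
    quantitative: bool = False
    exotic: np.ndarray = field(default=None)  # type: ignore[assignment]
    location: str = ""
    network_id: str = ""

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2:
            raise NetworkValidationError("weights must be a 2-D matrix")
        if w.shape != (len(self.plant_ids), len(self.pollinator_ids)):
            raise NetworkValidationError(
                f"weights shape {w.shape} does not match labels "
                f"({len(self.plant_ids)} plants, {len(self.pollinator_ids)} pollinators)"
            )
        if not np.all(np.isfinite(w)):
            raise NetworkValidationError("weights must be finite")
        if np.any(w < 0):
            raise NetworkValidationError("weights must be non-negative")
        if not self.quantitative and not np.all(np.isin(w, (0.0, 1.0))):
            raise NetworkValidationError(
                "qualitative network contains values outside {0, 1}"
            )
        if len(set(self.plant_ids)) != len(self.plant_ids):
            raise NetworkFormatError("duplicate plant labels")
        if len(set(self.pollinator_ids)) != len(self.pollinator_ids):
            raise NetworkFormatError("duplicate pollinator labels")
        exotic = self.exotic
        if exotic is None:
            exotic = np.zeros(len(self.plant_ids), dtype=bool)
        exotic = np.asarray(exotic, dtype=bool)
        if exotic.shape != (len(self.plant_ids),):
            raise NetworkValidationError("one exotic flag required per plant")
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "exotic", exotic)
        object.__setattr__(self, "plant_ids", tuple(str(p) for p in self.plant_ids))
        object.__setattr__(
            self, "pollinator_ids", tuple(str(a) for a in self.pollinator_ids)
        )

    # ---- basic structure -------------------------------------------------

    @property
    def n_plants(self) -> int:
        return len(self.plant_ids)

    @property
    def n_pollinators(self) -> int:
        return len(self.pollinator_ids)

    @property
    def binary(self) -> np.ndarray:
        """Binary (0/1 int) structure: weight > 0."""
        return (self.weights > 0).astype(int)

    @property
    def n_links(self) -> int:
        return int(self.binary.sum())

    @property
    def plant_degrees(self) -> np.ndarray:
        return self.binary.sum(axis=1)

    @property
    def pollinator_degrees(self) -> np.ndarray:
        return self.binary.sum(axis=0)

    def plant_index(self, label: str) -> int:
        try:
            return self.plant_ids.index(label)
        except ValueError:
            raise KeyError(f"unknown plant label: {label!r}") from None

    def pollinator_index(self, label: str) -> int:
        try:
            return self.pollinator_ids.index(label)
        except ValueError:
            raise KeyError(f"unknown pollinator label: {label!r}") from None

    def with_weights(self, weights: np.ndarray) -> "BipartiteNetwork":
        """Copy of this network with a replaced weight matrix."""
        return replace(self, weights=np.asarray(weights, dtype=float))

    def is_connected(self) -> bool:
        """True when every plant and pollinator has at least one link."""
        b = self.binary
        return bool(np.all(b.sum(axis=1) > 0) and np.all(b.sum(axis=0) > 0))


def drop_unconnected(network: BipartiteNetwork) -> BipartiteNetwork:
    """Remove zero-degree plants and pollinators; idempotent.

    Raises
    ------
    EmptyNetworkError
        If no plant or no pollinator survives.
    """
    b = network.binary
    keep_p = b.sum(axis=1) > 0
    keep_a = b.sum(axis=0) > 0
    if not keep_p.any() or not keep_a.any():
        raise EmptyNetworkError(
            f"network {network.network_id!r} has no connected species"
        )
    if keep_p.all() and keep_a.all():
        return network
    return BipartiteNetwork(
        plant_ids=tuple(np.array(network.plant_ids)[keep_p]),
        pollinator_ids=tuple(np.array(network.pollinator_ids)[keep_a]),
        weights=network.weights[np.ix_(keep_p, keep_a)],
        quantitative=network.quantitative,
        exotic=network.exotic[keep_p],
        location=network.location,
        network_id=network.network_id,
    )


# ---- on-disk formats -----------------------------------------------------


def _read_matrix_table(matrix_path: str | Path) -> pd.DataFrame:
    path = Path(matrix_path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]
    if len(set(header)) != len(header):
        raise NetworkFormatError(f"duplicate pollinator labels in {path}")
    try:
        table = pd.read_csv(path, sep=sep, index_col=0)
    except Exception as exc:  # pragma: no cover - pandas message varies
        raise NetworkFormatError(f"cannot parse matrix file {path}: {exc}") from exc
    if table.shape[1] == 0:
        raise NetworkFormatError(f"matrix file {path} has no pollinator columns")
    if table.index.isna().any() or any(str(c).startswith("Unnamed") for c in table.columns):
        raise NetworkFormatError(
            f"matrix file {path} must carry plant row labels and pollinator column labels"
        )
    return table


def read_network(
    matrix_path: str | Path, metadata_path: str | Path
) -> BipartiteNetwork:
    """Read a network from a labeled matrix file plus a metadata sidecar.

    The matrix is CSV/TSV with plants as rows and pollinators as columns.  The
    sidecar is YAML with keys ``network_id``, ``location``, ``quantitative``
    and ``exotic_plants`` (a list of row labels).  Exotic names are matched
    case-insensitively after whitespace normalization; names that match no
    row produce a warning and are ignored (they are never treated as exotic).
    """
    table = _read_matrix_table(matrix_path)
    with open(metadata_path) as fh:
        meta = yaml.safe_load(fh) or {}

    plant_ids = [str(p) for p in table.index]
    pollinator_ids = [str(a) for a in table.columns]
    if len(set(plant_ids)) != len(plant_ids):
        raise NetworkFormatError(f"duplicate plant labels in {matrix_path}")
    if len(set(pollinator_ids)) != len(pollinator_ids):
        raise NetworkFormatError(f"duplicate pollinator labels in {matrix_path}")

    weights = table.to_numpy(dtype=float)
    if np.any(weights < 0):
        raise NetworkValidationError(f"negative entry in {matrix_path}")

    lookup = {_normalize_name(p): i for i, p in enumerate(plant_ids)}
    exotic = np.zeros(len(plant_ids), dtype=bool)
    for name in meta.get("exotic_plants") or []:
        idx = lookup.get(_normalize_name(name))
        if idx is None:
            warnings.warn(
                f"exotic plant {name!r} not found among rows of {matrix_path}; "
                "it will not be considered exotic",
                stacklevel=2,
            )
        else:
            exotic[idx] = True

    return BipartiteNetwork(
        plant_ids=tuple(plant_ids),
        pollinator_ids=tuple(pollinator_ids),
        weights=weights,
        quantitative=bool(meta.get("quantitative", False)),
        exotic=exotic,
        location=str(meta.get("location", "")),
        network_id=str(meta.get("network_id", Path(matrix_path).stem)),
    )


def write_network(
    network: BipartiteNetwork, matrix_path: str | Path, metadata_path: str | Path
) -> None:
    """Write a network in the formats :func:`read_network` accepts."""
    path = Path(matrix_path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    frame = pd.DataFrame(
        network.weights,
        index=list(network.plant_ids),
        columns=list(network.pollinator_ids),
    )
    frame.to_csv(path, sep=sep)
    meta = {
        "network_id": network.network_id,
        "location": network.location,
        "quantitative": bool(network.quantitative),
        "exotic_plants": [
            p for p, flag in zip(network.plant_ids, network.exotic) if flag
        ],
    }
    with open(metadata_path, "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)


# ---- phylogeny -----------------------------------------------------------


class PhylogenyError(ValueError):
    """Phylogeny cannot be parsed or lacks required branch lengths."""


@dataclass
class PlantPhylogeny:
    """A rooted, dated plant phylogeny supporting patristic-distance queries."""

    tree: dendropy.Tree

    def __post_init__(self) -> None:
        for edge in self.tree.preorder_edge_iter():
            if edge.head_node is self.tree.seed_node:
                continue
            if edge.length is None:
                raise PhylogenyError(
                    "tree has edges without branch lengths; a dated tree is required"
                )
            if edge.length < 0:
                raise PhylogenyError("negative branch length")
        self._tips = {
            taxon.label: leaf
            for leaf in self.tree.leaf_node_iter()
            for taxon in [leaf.taxon]
            if taxon is not None
        }
        self._depths: dict[int, float] = {}
        for node in self.tree.preorder_node_iter():
            parent_depth = (
                self._depths[id(node.parent_node)] if node.parent_node else 0.0
            )
            self._depths[id(node)] = parent_depth + (node.edge.length or 0.0)

    @property
    def tip_labels(self) -> list[str]:
        return sorted(self._tips)

    def _tip(self, label: str) -> dendropy.Node:
        try:
            return self._tips[label]
        except KeyError:
            raise KeyError(f"taxon {label!r} not found on the tree") from None

    def depth(self, node: dendropy.Node) -> float:
        return self._depths[id(node)]

    def mrca(self, labels) -> dendropy.Node:
        nodes = {id(self._tip(lbl)) for lbl in labels}
        if not nodes:
            raise ValueError("empty taxon set")
        taxa = [self._tip(lbl).taxon for lbl in labels]
        if len(taxa) == 1:
            return self._tip(next(iter(labels)))
        return self.tree.mrca(taxa=taxa)

    def distance(self, a: str, b: str) -> float:
        """Patristic distance between two tips (sum of branch lengths)."""
        if a == b:
            return 0.0
        node_a, node_b = self._tip(a), self._tip(b)
        mrca = self.tree.mrca(taxa=[node_a.taxon, node_b.taxon])
        return (
            self.depth(node_a) + self.depth(node_b) - 2.0 * self.depth(mrca)
        )


def read_phylogeny(tree_path: str | Path) -> PlantPhylogeny:
    """Parse a Newick tree with branch lengths into a :class:`PlantPhylogeny`."""
    try:
        tree = dendropy.Tree.get(
            path=str(tree_path),
            schema="newick",
            preserve_underscores=True,
        )
        tree.is_rooted = True
    except Exception as exc:
        raise PhylogenyError(f"cannot parse Newick file {tree_path}: {exc}") from exc
    return PlantPhylogeny(tree=tree)


def phylogeny_from_string(newick: str) -> PlantPhylogeny:
    """Parse a Newick string (convenience twin of :func:`read_phylogeny`)."""
    try:
        tree = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True
        )
        tree.is_rooted = True
    except Exception as exc:
        raise PhylogenyError(f"cannot parse Newick string: {exc}") from exc
    return PlantPhylogeny(tree=tree)
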