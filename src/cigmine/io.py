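"""Readers and writers for all on-disk artifacts.

Formats (all plain text except the optional HDF5 structure container):

* domain table — TSV with BED-like leading columns
  ``chrom  start  end  domain_id  radius  category  [gene_density]  [expression]``;
  coordinates 0-based half-open.
* structure population — long-format TSV
  ``structure_id  domain_id  copy  x  y  z`` with ``copy`` in {A, B}; an
  optional comment header ``# nucleus_radius=<value>`` states the input unit,
  and coordinates are rescaled so that radius maps to 1.0. Rows of one
  structure must be contiguous (the reader streams structure by structure, so
  memory does not grow with K). Alternatively an HDF5 container with one
  ``/structures/<id>`` group holding an (N, 2, 3) ``coords`` dataset.
* contact lists — TSV ``structure_id  node1  node2`` with node labels
  ``L1-L2-L3`` (alternate input bypassing geometric contact calling).
* signal matrix — TSV, first column ``domain_id``, remaining columns factors.
* cluster sets — JSON with a ``schema_version`` field; round-trips bit-exactly.
"""

from __future__ import annotations

import json
import warnings
from typing import Iterator

import numpy as np
import pandas as pd

from .domains import DomainTable
from .errors import (
    CompletenessError,
    FormatError,
    UnsupportedVersionError,
    ValidationError,
)
from .graphs import CIG
from .isomorphism import CopySignature, FrequentCluster
from .population import StructurePopulation

CLUSTER_SCHEMA_VERSION = 1


# ---------------------------------------------------------------------------
# domain table
# ---------------------------------------------------------------------------

def read_domain_table(path) -> DomainTable:
    """Read and validate a TSV domain table; L1/L2 are assigned on load."""
    try:
        df = pd.read_csv(path, sep="\t", comment="#")
    except Exception as exc:  # noqa: BLE001 - rewrap with file context
        raise FormatError(f"{path}: cannot parse domain table: {exc}") from exc
    if "domain_id" in df.columns:
        dups = df.index[df["domain_id"].duplicated()]
        if len(dups):
            # +2: header line plus 1-based numbering
            raise FormatError(
                f"{path}: duplicate domain_id {df.loc[dups[0], 'domain_id']!r} "
                f"at line {dups[0] + 2}"
            )
    return DomainTable(df)


def write_domain_table(domains: DomainTable, path) -> None:
    cols = [c for c in domains.df.columns if c not in ("L1", "L2")]
    domains.df[cols].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# structure population
# ---------------------------------------------------------------------------

def _read_header_radius(path) -> float | None:
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                return None
            if "nucleus_radius=" in line:
                return float(line.split("nucleus_radius=")[1].strip())
    return None


def iter_structure_rows(path) -> Iterator[tuple[str, pd.DataFrame]]:
    """Stream (structure_id, rows) groups from a long-format TSV.

    Constant memory per structure: rows of one structure must be contiguous.
    """
    buf: list[list[str]] = []
    current = None
    cols = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if cols is None:
                cols = fields
                expected = ["structure_id", "domain_id", "copy", "x", "y", "z"]
                if cols[:6] != expected:
                    raise FormatError(
                        f"{path}:{lineno}: header must be {expected}, got {cols[:6]}"
                    )
                continue
            if len(fields) < 6:
                raise FormatError(f"{path}:{lineno}: expected 6 fields, got {len(fields)}")
            if current is not None and fields[0] != current:
                yield current, pd.DataFrame(buf, columns=cols)
                buf = []
            current = fields[0]
            buf.append(fields)
    if current is not None:
        yield current, pd.DataFrame(buf, columns=cols)


def read_structure_population(
    path, domains: DomainTable, nucleus_radius: float | None = None, tol: float = 0.05
) -> StructurePopulation:
    """Read a long-format TSV population, rescaling the nucleus to the unit sphere.

    Every (structure, domain, copy) must appear exactly once; a missing or
    duplicated record raises :class:`CompletenessError`. Sphere centres beyond
    the envelope by more than ``tol`` are kept but counted in a warning.
    """
    radius = nucleus_radius or _read_header_radius(path) or 1.0
    N = domains.n
    coords_list, ids = [], []
    n_outside = 0
    for sid, rows in iter_structure_rows(path):
        arr = np.full((N, 2, 3), np.nan)
        seen = set()
        for _, row in rows.iterrows():
            did, copy = row["domain_id"], row["copy"]
            if copy not in ("A", "B"):
                raise FormatError(f"{path}: structure {sid}: bad copy label {copy!r}")
            try:
                d = domains.index_of(did)
            except KeyError:
                raise ValidationError(
                    f"{path}: structure {sid}: unknown domain_id {did!r}"
                ) from None
            key = (d, copy)
            if key in seen:
                raise CompletenessError(
                    f"{path}: structure {sid}: duplicate record for {did}/{copy}"
                )
            seen.add(key)
            c = 0 if copy == "A" else 1
            arr[d, c] = [float(row["x"]), float(row["y"]), float(row["z"])]
        if len(seen) != 2 * N:
            missing = 2 * N - len(seen)
            raise CompletenessError(
                f"{path}: structure {sid}: {missing} (domain, copy) record(s) missing"
            )
        arr /= radius
        n_outside += int(
            (np.linalg.norm(arr, axis=-1) + domains.radii[:, None] > 1.0 + tol).sum()
        )
        coords_list.append(arr)
        ids.append(sid)
    if not coords_list:
        raise CompletenessError(f"{path}: no structures found")
    if n_outside:
        warnings.warn(
            f"{path}: {n_outside} sphere(s) extend beyond the nucleus by more "
            f"than tol={tol}; kept as-is",
            stacklevel=2,
        )
    return StructurePopulation(np.stack(coords_list), ids)


def write_structure_population(
    population: StructurePopulation, domains: DomainTable, path
) -> None:
    with open(path, "w") as fh:
        fh.write("# nucleus_radius=1.0\n")
        fh.write("structure_id\tdomain_id\tcopy\tx\ty\tz\n")
        for k, sid in enumerate(population.structure_ids):
            for d, did in enumerate(domains.domain_ids):
                for c, copy in enumerate("AB"):
                    x, y, z = population.coords[k, d, c]
                    fh.write(f"{sid}\t{did}\t{copy}\t{x:.8g}\t{y:.8g}\t{z:.8g}\n")


def write_structure_population_hdf5(
    population: StructurePopulation, domains: DomainTable, path
) -> None:
    """HDF5 dialect: one /structures/<id> group per structure."""
    import h5py

    with h5py.File(path, "w") as fh:
        fh.attrs["nucleus_radius"] = 1.0
        fh.create_dataset(
            "domain_ids", data=np.array(domains.domain_ids, dtype="S")
        )
        grp = fh.create_group("structures")
        for k, sid in enumerate(population.structure_ids):
            grp.create_group(sid).create_dataset("coords", data=population.coords[k])
        fh.create_dataset(
            "structure_order", data=np.array(population.structure_ids, dtype="S")
        )


def read_structure_population_hdf5(path, domains: DomainTable) -> StructurePopulation:
    import h5py

    with h5py.File(path, "r") as fh:
        radius = float(fh.attrs.get("nucleus_radius", 1.0))
        file_ids = [s.decode() for s in fh["domain_ids"][:]]
        if file_ids != domains.domain_ids:
            raise ValidationError(f"{path}: domain_id order does not match the table")
        order = [s.decode() for s in fh["structure_order"][:]]
        coords = np.stack([fh["structures"][sid]["coords"][:] for sid in order])
    return StructurePopulation(coords / radius, order)


# ---------------------------------------------------------------------------
# contact lists
# ---------------------------------------------------------------------------

def _parse_node(token: str, domains: DomainTable, where: str) -> int:
    parts = token.split("-")
    if len(parts) != 3 or parts[2] not in ("A", "B"):
        raise ValidationError(f"{where}: malformed node label {token!r}")
    try:
        d = domains.index_of_label(int(parts[0]), int(parts[1]))
    except (KeyError, ValueError):
        raise ValidationError(
            f"{where}: node {token!r} not in the domain universe"
        ) from None
    return 2 * d + (0 if parts[2] == "A" else 1)


def read_contact_lists(path, domains: DomainTable) -> list[CIG]:
    """Read per-structure edge lists (structure_id, L1-L2-L3, L1-L2-L3) into CIGs.

    Self-edges are rejected; duplicate rows collapse to a single edge.
    Structures appear in order of first appearance.
    """
    n_nodes = 2 * domains.n
    adj: dict[str, np.ndarray] = {}
    order: list[str] = []
    with open(path) as fh:
        header = None
        for lineno, line in enumerate(fh, 1):
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if header is None:
                header = fields
                continue
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected 3 fields")
            sid = fields[0]
            where = f"{path}:{lineno}"
            i = _parse_node(fields[1], domains, where)
            j = _parse_node(fields[2], domains, where)
            if i == j:
                raise ValidationError(f"{where}: self-edge {fields[1]!r}")
            if sid not in adj:
                adj[sid] = np.zeros((n_nodes, n_nodes), dtype=bool)
                order.append(sid)
            adj[sid][i, j] = adj[sid][j, i] = True
    return [CIG(sid, adj[sid]) for sid in order]


# ---------------------------------------------------------------------------
# signal matrix
# ---------------------------------------------------------------------------

def read_signal_matrix(path, domains: DomainTable) -> pd.DataFrame:
    """TSV of nonnegative factor signals; rows must cover exactly the domain set."""
    df = pd.read_csv(path, sep="\t", index_col="domain_id")
    if set(df.index) != set(domains.domain_ids):
        raise ValidationError(f"{path}: row set does not equal the domain_id set")
    vals = df.to_numpy(float)
    if not np.isfinite(vals).all() or (vals < 0).any():
        raise ValidationError(f"{path}: signals must be finite and >= 0")
    return df.loc[domains.domain_ids]


def write_signal_matrix(signals: pd.DataFrame, path) -> None:
    signals.to_csv(path, sep="\t", index_label="domain_id")


# ---------------------------------------------------------------------------
# cluster sets
# ---------------------------------------------------------------------------

def _occurrence_to_indices(vec: np.ndarray) -> list[int]:
    return [int(i) for i in np.flatnonzero(vec)]


def write_clusters(
    clusters: list[FrequentCluster],
    path,
    K: int,
    params: dict | None = None,
) -> None:
    """Serialize a cluster set to versioned JSON (deterministic byte layout)."""
    obj = {
        "schema_version": CLUSTER_SCHEMA_VERSION,
        "n_structures": K,
        "params": params or {},
        "clusters": [
            {
                "cluster_id": c.cluster_id,
                "members": list(c.members),
                "signature": c.signature.to_json(),
                "occurrence": _occurrence_to_indices(c.occurrence),
                "mean_density": c.mean_density,
                "n_chromosomes": c.n_chromosomes,
                "centromeric_proportion": c.centromeric_proportion,
            }
            for c in clusters
        ],
    }
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_clusters(path) -> tuple[list[FrequentCluster], int, dict]:
    """Read a cluster-set JSON; returns (clusters, K, params)."""
    try:
        with open(path) as fh:
            obj = json.load(fh)
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: truncated or malformed cluster JSON: {exc}") from exc
    version = obj.get("schema_version")
    if version != CLUSTER_SCHEMA_VERSION:
        raise UnsupportedVersionError(
            f"{path}: schema_version {version!r} unsupported "
            f"(expected {CLUSTER_SCHEMA_VERSION})"
        )
    K = int(obj["n_structures"])
    clusters = []
    for c in obj["clusters"]:
        vec = np.zeros(K, dtype=bool)
        vec[np.asarray(c["occurrence"], dtype=int)] = True
        clusters.append(
            FrequentCluster(
                cluster_id=c["cluster_id"],
                members=tuple(c["members"]),
                signature=CopySignature.from_json(c["signature"]),
                occurrence=vec,
                mean_density=float(c["mean_density"]),
                n_chromosomes=int(c["n_chromosomes"]),
                centromeric_proportion=float(c["centromeric_proportion"]),
            )
        )
    return clusters, K, obj.get("params", {})


def write_cluster_summary(clusters: list[FrequentCluster], path) -> None:
    """One-row-per-cluster TSV summary."""
    with open(path, "w") as fh:
        fh.write(
            "cluster_id\tmembers\tsignature\tsize\tfrequency\tmean_density\t"
            "n_chromosomes\tcentromeric_proportion\n"
        )
        for c in clusters:
            fh.write(
                f"{c.cluster_id}\t{','.join(c.members)}\t{c.signature}\t{c.size}\t"
                f"{c.frequency:.6g}\t{c.mean_density:.6g}\t{c.n_chromosomes}\t"
                f"{c.centromeric_proportion:.6g}\n"
            )
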