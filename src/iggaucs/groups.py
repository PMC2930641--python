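"""Group (pathway) structure over feature indices and the GMT reader.

A :class:`GroupStructure` is a partition of the feature index set into r
disjoint groups (gene pathways, variable clusters), each with a
nonnegative weight d_l used by the group penalty. The on-disk format is a
GMT dialect: one line per group with ``name <TAB> description <TAB>
member1 <TAB> member2 ...``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["GroupStructure", "load_groups", "contiguous_groups", "expand_overlaps"]


@dataclass
class GroupStructure:
    """Partition of feature indices into weighted groups.

    Parameters
    ----------
    indices : list of ndarray
        One integer index array per group; arrays are disjoint.
    names : list of str, optional
        Group labels, default ``g1..gr``.
    d : ndarray, optional
        Nonnegative group weights d_l; default all ones (all groups equally
        important). Use :meth:`with_size_weights` for sqrt(m_l) scaling.
    """

    indices: list[np.ndarray]
    names: list[str] = field(default_factory=list)
    d: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.indices = [np.asarray(ix, dtype=int) for ix in self.indices]
        if not self.indices:
            raise ValueError("need at least one group")
        if any(len(ix) == 0 for ix in self.indices):
            raise ValueError("empty group")
        flat = np.concatenate(self.indices)
        if len(np.unique(flat)) != len(flat):
            raise ValueError("groups must be disjoint (a feature appears twice)")
        if not self.names:
            self.names = [f"g{l + 1}" for l in range(len(self.indices))]
        if len(self.names) != len(self.indices):
            raise ValueError("names length must match number of groups")
        if self.d is None:
            self.d = np.ones(len(self.indices))
        self.d = np.asarray(self.d, dtype=float)
        if len(self.d) != len(self.indices) or np.any(self.d < 0):
            raise ValueError("d must hold one nonnegative weight per group")

    @property
    def r(self) -> int:
        return len(self.indices)

    @property
    def sizes(self) -> np.ndarray:
        return np.array([len(ix) for ix in self.indices])

    @property
    def n_features(self) -> int:
        return int(self.sizes.sum())

    def group_norms(self, w: np.ndarray) -> np.ndarray:
        """Per-group Euclidean norms ||w_l|| of a coefficient vector."""
        w = np.asarray(w, dtype=float)
        return np.array([np.linalg.norm(w[ix]) for ix in self.indices])

    def with_size_weights(self) -> "GroupStructure":
        """Return a copy with d_l = sqrt(m_l) (conventional size scaling)."""
        return GroupStructure(
            indices=[ix.copy() for ix in self.indices],
            names=list(self.names),
            d=np.sqrt(self.sizes.astype(float)),
        )


def contiguous_groups(m: int, group_size: int, names: list[str] | None = None) -> GroupStructure:
    """Partition features 0..m-1 into consecutive blocks of equal size."""
    if m % group_size:
        raise ValueError("m must be a multiple of group_size")
    idx = [np.arange(i, i + group_size) for i in range(0, m, group_size)]
    return GroupStructure(indices=idx, names=names or [])


def load_groups(
    gmt_path: str,
    feature_ids: list[str],
    allow_overlap: bool = False,
) -> GroupStructure:
    """Read a GMT group file against an available feature list.

    Listed members absent from ``feature_ids`` are dropped with a warning;
    groups left empty are removed. Features never listed form no group and
    are excluded from fitting. A feature listed under two groups is an
    error unless ``allow_overlap`` (see :func:`expand_overlaps` for the
    duplication workaround).
    """
    pos = {f: i for i, f in enumerate(feature_ids)}
    names: list[str] = []
    indices: list[np.ndarray] = []
    seen: dict[str, str] = {}
    n_dropped = 0
    with open(gmt_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"{gmt_path}:{lineno}: GMT line needs name, description, members"
                )
            name, members = parts[0], [p for p in parts[2:] if p]
            idx = []
            for g in members:
                if g not in pos:
                    n_dropped += 1
                    continue
                if g in seen and not allow_overlap:
                    raise ValueError(
                        f"{gmt_path}:{lineno}: feature {g!r} already in group "
                        f"{seen[g]!r}; the penalty assumes a partition "
                        "(use expand_overlaps to duplicate shared features)"
                    )
                if g not in seen or not allow_overlap:
                    idx.append(pos[g])
                seen.setdefault(g, name)
            if idx:
                names.append(name)
                indices.append(np.array(sorted(set(idx))))
    if n_dropped:
        logger.warning("dropped %d listed features absent from the matrix", n_dropped)
    if not indices:
        raise ValueError(f"{gmt_path}: no usable groups")
    return GroupStructure(indices=indices, names=names)


def expand_overlaps(
    X: np.ndarray,
    feature_ids: list[str],
    membership: list[tuple[str, list[str]]],
) -> tuple[np.ndarray, list[str], GroupStructure]:
    """Duplicate features shared by several groups so groups partition.

    The penalty model requires disjoint groups; real pathway databases
    overlap. This preprocessing replicates a shared feature's column once
    per group it belongs to, returning the expanded matrix, new feature
    labels (``gene@group``) and the disjoint structure.
    """
    pos = {f: i for i, f in enumerate(feature_ids)}
    cols: list[int] = []
    new_ids: list[str] = []
    indices: list[np.ndarray] = []
    names: list[str] = []
    for name, members in membership:
        idx = []
        for g in members:
            if g not in pos:
                continue
            idx.append(len(cols))
            cols.append(pos[g])
            new_ids.append(f"{g}@{name}")
        if idx:
            names.append(name)
            indices.append(np.array(idx))
    if not indices:
        raise ValueError("no usable groups after matching features")
    return X[:, cols], new_ids, GroupStructure(indices=indices, names=names)
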