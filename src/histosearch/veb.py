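"""Van Emde Boas tree over a fixed integer universe.

The search index of the slide database is a set of integers bounded by a
universe constant ``M`` (a power of two chosen so that every composable
patch index fits below it).  A van Emde Boas (vEB) tree supports insert,
delete, membership, successor and predecessor in ``O(log log M)`` time,
independent of how many keys are stored — the property that makes whole
database search run in constant time with respect to database size.

Clusters are allocated lazily, so memory scales with the number of stored
keys rather than with ``M``.  Successor/predecessor are *strict*: they
return the nearest stored key strictly greater/less than the probe, or
``None``.
"""

from __future__ import annotations

from typing import Iterable, Iterator, Optional

__all__ = ["VebTree", "UNIVERSE_BITS", "UNIVERSE_SIZE"]

#: Default universe: smallest power of two exceeding the maximum patch index.
UNIVERSE_BITS = 50
UNIVERSE_SIZE = 1 << UNIVERSE_BITS


class _Node:
    """One vEB node over a ``bits``-wide sub-universe.

    ``min``/``max`` are stored locally; ``min`` is *not* recursively stored
    in a cluster (classic van Emde Boas layout), which is what makes every
    operation a single recursive call per level.
    """

    __slots__ = ("bits", "lo_bits", "lo_mask", "min", "max", "summary", "clusters")

    def __init__(self, bits: int) -> None:
        self.bits = bits
        self.lo_bits = bits >> 1
        self.lo_mask = (1 << self.lo_bits) - 1
        self.min: Optional[int] = None
        self.max: Optional[int] = None
        self.summary: Optional[_Node] = None
        self.clusters: dict[int, _Node] = {}

    # -- coordinate helpers ------------------------------------------------
    def _high(self, x: int) -> int:
        return x >> self.lo_bits

    def _low(self, x: int) -> int:
        return x & self.lo_mask

    def _index(self, high: int, low: int) -> int:
        return (high << self.lo_bits) | low

    # -- operations ----------------------------------------------------------
    def insert(self, x: int) -> None:
        if self.min is None:
            self.min = self.max = x
            return
        if x == self.min or x == self.max:
            return
        if x < self.min:
            x, self.min = self.min, x
        if self.bits > 1:
            h, l = self._high(x), self._low(x)
            cluster = self.clusters.get(h)
            if cluster is None:
                cluster = _Node(self.lo_bits)
                self.clusters[h] = cluster
            if cluster.min is None:
                if self.summary is None:
                    self.summary = _Node(self.bits - self.lo_bits)
                self.summary.insert(h)
            cluster.insert(l)
        if x > self.max:
            self.max = x

    def member(self, x: int) -> bool:
        if x == self.min or x == self.max:
            return True
        if self.bits == 1:
            return False
        cluster = self.clusters.get(self._high(x))
        return cluster is not None and cluster.member(self._low(x))

    def successor(self, x: int) -> Optional[int]:
        if self.bits == 1:
            if x == 0 and self.max == 1:
                return 1
            return None
        if self.min is not None and x < self.min:
            return self.min
        h, l = self._high(x), self._low(x)
        cluster = self.clusters.get(h)
        if cluster is not None and cluster.max is not None and l < cluster.max:
            return self._index(h, cluster.successor(l))
        succ_cluster = self.summary.successor(h) if self.summary is not None else None
        if succ_cluster is None:
            return None
        return self._index(succ_cluster, self.clusters[succ_cluster].min)

    def predecessor(self, x: int) -> Optional[int]:
        if self.bits == 1:
            if x == 1 and self.min == 0:
                return 0
            return None
        if self.max is not None and x > self.max:
            return self.max
        h, l = self._high(x), self._low(x)
        cluster = self.clusters.get(h)
        if cluster is not None and cluster.min is not None and l > cluster.min:
            return self._index(h, cluster.predecessor(l))
        pred_cluster = self.summary.predecessor(h) if self.summary is not None else None
        if pred_cluster is None:
            if self.min is not None and x > self.min:
                return self.min
            return None
        return self._index(pred_cluster, self.clusters[pred_cluster].max)

    def delete(self, x: int) -> None:
        if self.min == self.max:
            # single key in this node
            self.min = self.max = None
            return
        if self.bits == 1:
            self.min = self.max = 1 - x
            return
        if x == self.min:
            # pull the new minimum out of the first cluster
            first = self.summary.min  # summary non-empty: node holds >= 2 keys
            x = self._index(first, self.clusters[first].min)
            self.min = x
        h, l = self._high(x), self._low(x)
        cluster = self.clusters.get(h)
        if cluster is None or not cluster.member(l):
            return
        cluster.delete(l)
        if cluster.min is None:
            del self.clusters[h]
            self.summary.delete(h)
            if self.summary.min is None:
                self.summary = None
            if x == self.max:
                self.max = self.min if self.summary is None else self._index(
                    self.summary.max, self.clusters[self.summary.max].max
                )
        elif x == self.max:
            self.max = self._index(h, cluster.max)


class VebTree:
    """Integer set over the fixed universe ``[0, 2**bits)``.

    Duplicates are stored once (re-insert is a no-op); deleting an absent
    key is a no-op.  ``successor``/``predecessor`` use strict semantics.
    """

    def __init__(self, bits: int = UNIVERSE_BITS) -> None:
        if bits < 1:
            raise ValueError("universe must span at least one bit")
        self._root = _Node(bits)
        self.bits = bits
        self.universe_size = 1 << bits
        self._count = 0

    def _check(self, key: int) -> None:
        if not (0 <= key < self.universe_size):
            raise ValueError(
                f"key {key} outside universe [0, {self.universe_size})"
            )

    def __len__(self) -> int:
        return self._count

    def __contains__(self, key: int) -> bool:
        return self.member(key)

    def member(self, key: int) -> bool:
        self._check(key)
        return self._root.member(key)

    def insert(self, key: int) -> None:
        self._check(key)
        if not self._root.member(key):
            self._root.insert(key)
            self._count += 1

    def delete(self, key: int) -> None:
        self._check(key)
        if self._root.member(key):
            self._root.delete(key)
            self._count -= 1

    def successor(self, key: int) -> Optional[int]:
        """Smallest stored key strictly greater than ``key``, or ``None``."""
        self._check(key)
        return self._root.successor(key)

    def predecessor(self, key: int) -> Optional[int]:
        """Largest stored key strictly less than ``key``, or ``None``."""
        self._check(key)
        return self._root.predecessor(key)

    @property
    def min(self) -> Optional[int]:
        return self._root.min

    @property
    def max(self) -> Optional[int]:
        return self._root.max

    def __iter__(self) -> Iterator[int]:
        key = self._root.min
        while key is not None:
            yield key
            key = self._root.successor(key)

    @classmethod
    def from_keys(cls, keys: Iterable[int], bits: int = UNIVERSE_BITS) -> "VebTree":
        tree = cls(bits)
        for k in keys:
            tree.insert(int(k))
        return tree
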