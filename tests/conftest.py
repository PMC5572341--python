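"""Shared fixtures and independent brute-force oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from cnvherd.calls import CnvCall
from cnvherd.signal import ProbeMap, SignalMatrix


def make_probes(
    n: int,
    chrom: int | list[int] = 1,
    spacing: int = 5_000,
    gc: np.ndarray | None = None,
) -> ProbeMap:
    """A simple evenly spaced probe map for unit tests."""
    chroms = np.full(n, chrom) if np.isscalar(chrom) else np.asarray(chrom)
    pos = np.empty(n, dtype=np.int64)
    for c in np.unique(chroms):
        mask = chroms == c
        pos[mask] = (np.arange(mask.sum()) + 1) * spacing
    ids = np.array([f"p{c}_{p}" for c, p in zip(chroms, pos)], dtype=object)
    return ProbeMap(probe_id=ids, chrom=chroms, pos=pos, gc=gc)


def make_signal(
    lrr: np.ndarray,
    baf: np.ndarray | None = None,
    probes: ProbeMap | None = None,
    gc: np.ndarray | None = None,
    spacing: int = 5_000,
) -> SignalMatrix:
    lrr = np.asarray(lrr, dtype=float)
    if baf is None:
        baf = np.full_like(lrr, 0.5)
    if probes is None:
        probes = make_probes(lrr.shape[0], gc=gc, spacing=spacing)
    samples = tuple(f"S{j + 1}" for j in range(lrr.shape[1]))
    return SignalMatrix(probes=probes, samples=samples, lrr=lrr, baf=baf)


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        self.parent[self.find(i)] = self.find(j)


def bitmap_cnvr_oracle(calls: list[CnvCall], n_samples_cohort: int):
    """Brute-force CNVR construction by painting calls onto a base-pair bitmap.

    For every base position, all calls covering it are merged (union-find), so
    components are exactly the transitive >= 1 bp overlap classes.  Returns
    (regions, singleton_clusters) where each region is a dict with span,
    support set and class -- deliberately independent of the package's sweep
    implementation.
    """
    uf = _UnionFind(len(calls))
    by_chrom: dict[int, list[int]] = {}
    for i, c in enumerate(calls):
        by_chrom.setdefault(c.chrom, []).append(i)
    for idxs in by_chrom.values():
        lo = min(calls[i].start for i in idxs)
        hi = max(calls[i].end for i in idxs)
        owner = [-1] * (hi - lo + 1)
        for i in idxs:
            c = calls[i]
            for p in range(c.start - lo, c.end - lo + 1):
                if owner[p] != -1:
                    uf.union(i, owner[p])
                owner[p] = i
    comps: dict[int, list[CnvCall]] = {}
    for i, c in enumerate(calls):
        comps.setdefault(uf.find(i), []).append(c)
    regions, singles = [], []
    for members in comps.values():
        samples = {c.sample_id for c in members}
        if len(samples) >= 2:
            states = {c.copy_state for c in members}
            if all(s < 2 for s in states):
                klass = "loss"
            elif all(s > 2 for s in states):
                klass = "gain"
            else:
                klass = "complex"
            regions.append(
                {
                    "chrom": members[0].chrom,
                    "start": min(c.start for c in members),
                    "end": max(c.end for c in members),
                    "support": frozenset(samples),
                    "klass": klass,
                }
            )
        else:
            singles.append(members)
    regions.sort(key=lambda r: (r["chrom"], r["start"]))
    return regions, singles


def random_call_instance(rng: np.random.Generator, max_calls: int = 50,
                         max_coord: int = 10_000) -> list[CnvCall]:
    """A random small call set for oracle-equivalence checks."""
    n = int(rng.integers(1, max_calls + 1))
    samples = [f"S{k}" for k in range(1, 9)]
    calls = []
    for _ in range(n):
        start = int(rng.integers(1, max_coord - 200))
        length = int(rng.integers(1, 201))
        calls.append(
            CnvCall(
                sample_id=samples[int(rng.integers(0, len(samples)))],
                chrom=int(rng.integers(1, 3)),
                start=start,
                end=min(start + length - 1, max_coord),
                copy_state=int(rng.choice([0, 1, 3, 4])),
                n_probes=int(rng.integers(3, 20)),
            )
        )
    return calls


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20_240_917)
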