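"""Combinatorial smFISH codebooks.

Each gene is encoded by a fixed-weight binary code laid out over
``n_rounds x n_channels`` imaging slots (round-major, channel-minor
slot order).  A subset of valid codes is deliberately left unassigned
("unused codes"); decoded hits landing on those codes estimate the
false-positive rate of the experiment.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["CodebookSpec", "Codebook", "make_codebook", "read_codebook", "write_codebook"]


@dataclass(frozen=True)
class CodebookSpec:
    """Parameters for codebook generation.

    Defaults mirror a two-color, eight-round acquisition (16 slots)
    with weight-4 codes at minimum pairwise Hamming distance 4.
    """

    n_genes: int
    n_rounds: int = 8
    n_channels: int = 2
    code_weight: int = 4
    min_hamming: int = 4
    n_unused: int = 0
    seed: int = 0

    @property
    def n_slots(self) -> int:
        return self.n_rounds * self.n_channels

    def validate(self) -> None:
        if self.n_rounds < 1 or self.n_channels < 1:
            raise ValueError("n_rounds and n_channels must be >= 1")
        if not (1 <= self.code_weight <= self.n_slots):
            raise ValueError(
                f"code_weight must be in [1, {self.n_slots}], got {self.code_weight}"
            )
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.n_unused < 0:
            raise ValueError("n_unused must be >= 0")
        if self.min_hamming < 0:
            raise ValueError("min_hamming must be >= 0")


@dataclass
class Codebook:
    """Gene -> binary code mapping plus reserved unused codes.

    ``codes`` has shape (n_genes, n_slots); ``unused_codes`` has shape
    (n_unused, n_slots).  All rows are distinct, carry the same weight
    and respect the pairwise minimum Hamming distance of the generating
    spec.
    """

    genes: list[str]
    codes: np.ndarray
    unused_codes: np.ndarray
    n_rounds: int = 8
    n_channels: int = 2

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.uint8)
        self.unused_codes = np.asarray(self.unused_codes, dtype=np.uint8)
        if self.unused_codes.size == 0:
            self.unused_codes = self.unused_codes.reshape(0, self.codes.shape[1])

    @property
    def n_slots(self) -> int:
        return self.codes.shape[1]

    @property
    def code_weight(self) -> int:
        return int(self.codes[0].sum())

    def code_for(self, gene: str) -> np.ndarray:
        try:
            i = self.genes.index(gene)
        except ValueError:
            raise KeyError(f"gene {gene!r} not in codebook") from None
        return self.codes[i]

    def on_slots(self, gene: str) -> np.ndarray:
        """Indices of the on-bit (round-major) slots for *gene*."""
        return np.flatnonzero(self.code_for(gene))

    def all_codes(self) -> np.ndarray:
        return np.vstack([self.codes, self.unused_codes])

    def validate(self, min_hamming: int | None = None) -> None:
        allc = self.all_codes()
        weights = allc.sum(axis=1)
        if not np.all(weights == weights[0]):
            raise ValueError("codes do not share a single weight")
        if len({tuple(r) for r in allc}) != len(allc):
            raise ValueError("duplicate codes present")
        if min_hamming is not None and len(allc) > 1:
            d = _pairwise_hamming(allc)
            if d.min() < min_hamming:
                raise ValueError(f"minimum pairwise Hamming {d.min()} < {min_hamming}")


def _pairwise_hamming(codes: np.ndarray) -> np.ndarray:
    """Condensed vector of pairwise Hamming distances."""
    c = codes.astype(np.int16)
    full = np.abs(c[:, None, :] - c[None, :, :]).sum(axis=2)
    iu = np.triu_indices(len(c), k=1)
    return full[iu]


def make_codebook(spec: CodebookSpec, gene_names: list[str] | None = None) -> Codebook:
    """Generate a codebook by randomized greedy code selection.

    Candidate codes of the requested weight are visited in a seeded
    random order; a candidate is kept when its Hamming distance to all
    previously kept codes is at least ``spec.min_hamming``.  Raises
    ``ValueError`` when the requested number of codes is infeasible.

    ``gene_names`` overrides the first ``len(gene_names)`` generated
    gene identifiers (e.g. to name marker genes in synthetic scenes).
    """
    spec.validate()
    if gene_names is not None and len(gene_names) > spec.n_genes:
        raise ValueError("more gene names than genes")
    n_needed = spec.n_genes + spec.n_unused
    rng = np.random.default_rng(spec.seed)

    n_candidates = _n_choose_k(spec.n_slots, spec.code_weight)
    if n_needed > n_candidates:
        raise ValueError(
            f"requested {n_needed} codes but only {n_candidates} "
            f"weight-{spec.code_weight} codes exist over {spec.n_slots} slots"
        )

    candidates = np.array(
        [
            _support_to_code(support, spec.n_slots)
            for support in itertools.combinations(range(spec.n_slots), spec.code_weight)
        ],
        dtype=np.uint8,
    )
    order = rng.permutation(len(candidates))

    kept: list[np.ndarray] = []
    kept_mat = np.empty((0, spec.n_slots), dtype=np.int16)
    for idx in order:
        cand = candidates[idx]
        if len(kept) and np.abs(kept_mat - cand.astype(np.int16)).sum(axis=1).min() < spec.min_hamming:
            continue
        kept.append(cand)
        kept_mat = np.vstack([kept_mat, cand.astype(np.int16)])
        if len(kept) == n_needed:
            break

    if len(kept) < n_needed:
        # Random visit orders can stall well below the best packing; the
        # lexicographic visit order is far denser (it attains the maximum
        # 140 for weight-4 / distance-4 codes over 16 slots), so fall back
        # to that pool and draw a seeded random subset from it.
        pool: list[np.ndarray] = []
        pool_mat = np.empty((0, spec.n_slots), dtype=np.int16)
        for cand in candidates:
            if len(pool) and np.abs(pool_mat - cand.astype(np.int16)).sum(axis=1).min() < spec.min_hamming:
                continue
            pool.append(cand)
            pool_mat = np.vstack([pool_mat, cand.astype(np.int16)])
        if len(pool) < n_needed:
            raise ValueError(
                f"could not place {n_needed} codes at min Hamming {spec.min_hamming}: "
                f"greedy selection found only {len(pool)}"
            )
        pick = rng.choice(len(pool), size=n_needed, replace=False)
        kept = [pool[i] for i in pick]

    codes = np.array(kept[: spec.n_genes], dtype=np.uint8)
    unused = np.array(kept[spec.n_genes :], dtype=np.uint8).reshape(spec.n_unused, spec.n_slots)
    genes = [f"GENE{i:03d}" for i in range(spec.n_genes)]
    if gene_names is not None:
        genes[: len(gene_names)] = gene_names
    cb = Codebook(genes, codes, unused, n_rounds=spec.n_rounds, n_channels=spec.n_channels)
    cb.validate(min_hamming=spec.min_hamming)
    return cb


def _support_to_code(support: tuple[int, ...], n: int) -> np.ndarray:
    code = np.zeros(n, dtype=np.uint8)
    code[list(support)] = 1
    return code


def _n_choose_k(n: int, k: int) -> int:
    import math

    return math.comb(n, k)


def write_codebook(cb: Codebook, path) -> None:
    """Write gene,code,used CSV.  Code strings are round-major, channel-minor."""
    rows = []
    for g, c in zip(cb.genes, cb.codes):
        rows.append({"gene": g, "code": "".join(map(str, c)), "used": 1})
    for i, c in enumerate(cb.unused_codes):
        rows.append({"gene": f"UNUSED{i:03d}", "code": "".join(map(str, c)), "used": 0})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_codebook(path, n_rounds: int = 8, n_channels: int = 2) -> Codebook:
    df = pd.read_csv(path, dtype={"code": str})
    n_slots = n_rounds * n_channels
    codes, unused, genes = [], [], []
    for row_idx, row in df.iterrows():
        code = str(row["code"])
        if len(code) != n_slots or set(code) - {"0", "1"}:
            raise ValueError(
                f"row {row_idx}: code {code!r} is not a binary string of length {n_slots}"
            )
        bits = np.frombuffer(code.encode(), dtype=np.uint8) - ord("0")
        if int(row["used"]):
            genes.append(str(row["gene"]))
            codes.append(bits)
        else:
            unused.append(bits)
    codes_arr = np.array(codes, dtype=np.uint8).reshape(len(codes), n_slots)
    unused_arr = np.array(unused, dtype=np.uint8).reshape(len(unused), n_slots)
    return Codebook(genes, codes_arr, unused_arr, n_rounds=n_rounds, n_channels=n_channels)
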