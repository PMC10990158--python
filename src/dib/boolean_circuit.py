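"""Boolean circuits and their exact information content.

A circuit is a DAG of two-operand AND/OR/XOR gates over binary inputs.
Enumerating its truth table under a uniform input distribution gives the
exact joint p(x1..xN, y), from which the mutual information between any
subset of inputs and the output is computed in closed form.  These exact
values are the ground truth against which the learned compression schemes
are compared: the upper envelope of I(X_S; Y) over subsets of each size is
the discrete frontier that an optimal sweep should trace.

All information is in bits (log base 2).  Input index 1 is the most
significant bit of the lexicographic row ordering.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BooleanCircuit",
    "TruthTable",
    "SubsetInformation",
    "generate_circuit",
    "truth_table",
    "subset_information",
    "subset_frontier",
]

_OPS = ("AND", "OR", "XOR")

_MAX_ENUM_INPUTS = 20
_MAX_FRONTIER_INPUTS = 14


class EnumerationTooLarge(ValueError):
    """Raised when a requested exhaustive enumeration exceeds the guard."""


@dataclass(frozen=True)
class BooleanCircuit:
    """Feed-forward circuit; node ids: 0..n_inputs-1 are inputs, gate i is node n_inputs+i."""

    n_inputs: int
    gates: tuple  # tuple of (op, (a, b)) with a, b earlier node ids
    output_node: int

    def __post_init__(self):
        n = self.n_inputs
        for i, (op, args) in enumerate(self.gates):
            if op not in _OPS:
                raise ValueError(f"unknown gate operator {op!r}")
            if len(args) < 2:
                raise ValueError("gates need at least two operands")
            if any(a >= n + i or a < 0 for a in args):
                raise ValueError("gate operands must reference earlier nodes (DAG)")
        if not (0 <= self.output_node < n + len(self.gates)):
            raise ValueError("output_node does not exist")

    @property
    def n_nodes(self) -> int:
        return self.n_inputs + len(self.gates)

    def evaluate(self, inputs: np.ndarray) -> np.ndarray:
        """Evaluate on a (batch, n_inputs) 0/1 array; returns (batch,) output bits."""
        inputs = np.asarray(inputs, dtype=np.uint8)
        if inputs.ndim == 1:
            inputs = inputs[None, :]
        vals = [inputs[:, i] for i in range(self.n_inputs)]
        for op, args in self.gates:
            a, b = vals[args[0]], vals[args[1]]
            if op == "AND":
                v = a & b
            elif op == "OR":
                v = a | b
            else:
                v = a ^ b
            vals.append(v)
        return vals[self.output_node]

    def input_ancestors(self) -> set:
        """Input ids that are ancestors of the output node."""
        needed = {self.output_node}
        for i in range(len(self.gates) - 1, -1, -1):
            node = self.n_inputs + i
            if node in needed:
                needed.update(self.gates[i][1])
        return {n for n in needed if n < self.n_inputs}

    # ------------------------------------------------------------------- io
    def to_json(self) -> str:
        return json.dumps(
            {
                "n_inputs": self.n_inputs,
                "gates": [{"op": op, "args": list(args)} for op, args in self.gates],
                "output": self.output_node,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "BooleanCircuit":
        d = json.loads(text)
        gates = tuple((g["op"], tuple(g["args"])) for g in d["gates"])
        return cls(n_inputs=d["n_inputs"], gates=gates, output_node=d["output"])


@dataclass
class TruthTable:
    """All 2^N input rows with output bit and row probabilities."""

    n_inputs: int
    inputs: np.ndarray  # (2^N, N) uint8, lexicographic, x1 = MSB
    outputs: np.ndarray  # (2^N,) uint8
    probs: np.ndarray  # (2^N,) float, sums to 1

    def __post_init__(self):
        m = 2**self.n_inputs
        if self.inputs.shape != (m, self.n_inputs) or self.outputs.shape != (m,):
            raise ValueError("truth table must have exactly 2^N rows")
        if abs(self.probs.sum() - 1.0) > 1e-12:
            raise ValueError("row probabilities must sum to 1")

    def output_entropy(self) -> float:
        """H(Y) in bits."""
        p1 = float(self.probs[self.outputs == 1].sum())
        return _binary_entropy(p1)

    def to_csv(self, path) -> None:
        cols = {f"x{i+1}": self.inputs[:, i] for i in range(self.n_inputs)}
        cols["y"] = self.outputs
        cols["prob"] = self.probs
        pd.DataFrame(cols).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "TruthTable":
        df = pd.read_csv(path)
        xcols = [c for c in df.columns if c.startswith("x")]
        n = len(xcols)
        return cls(
            n_inputs=n,
            inputs=df[[f"x{i+1}" for i in range(n)]].to_numpy(dtype=np.uint8),
            outputs=df["y"].to_numpy(dtype=np.uint8),
            probs=df["prob"].to_numpy(dtype=float),
        )


@dataclass(frozen=True)
class SubsetInformation:
    subset: frozenset
    mi_bits: float


def _binary_entropy(p: float) -> float:
    if p <= 0.0 or p >= 1.0:
        return 0.0
    return float(-p * np.log2(p) - (1 - p) * np.log2(1 - p))


def generate_circuit(n_inputs: int, n_gates: int, seed: int) -> BooleanCircuit:
    """Draw a random circuit in which every input feeds the output.

    Each gate picks an operator uniformly from AND/OR/XOR and two distinct
    earlier nodes.  The first operand is drawn from the pool of nodes not
    yet consumed by any gate, which guarantees (when slots suffice) that
    every node chains forward to the final gate; circuits that still leave
    an input disconnected are redrawn.
    """
    if n_inputs < 1 or n_gates < 1:
        raise ValueError("n_inputs and n_gates must be positive")
    rng = np.random.default_rng(seed)
    for _ in range(10_000):
        gates = []
        unused = list(range(n_inputs))
        for gi in range(n_gates):
            n_nodes = n_inputs + gi
            if unused:
                j = int(rng.integers(len(unused)))
                a = unused.pop(j)
            else:
                a = int(rng.integers(n_nodes))
            # force the second operand from the unconsumed pool when the
            # remaining gates could not otherwise consume it: with R gates
            # left, each consumes two nodes but adds one, so the pool
            # (including this gate's own node) must stay within R + 1
            remaining = n_gates - 1 - gi
            if unused and len(unused) > remaining:
                j = int(rng.integers(len(unused)))
                b = unused.pop(j)
            else:
                b = int(rng.integers(n_nodes))
                while b == a:
                    b = int(rng.integers(n_nodes))
                if b in unused:
                    unused.remove(b)
            op = _OPS[int(rng.integers(3))]
            gates.append((op, (a, b)))
            unused.append(n_nodes)  # the new gate itself awaits a consumer
        unused.remove(n_inputs + n_gates - 1)  # final gate feeds the output
        circuit = BooleanCircuit(
            n_inputs=n_inputs, gates=tuple(gates), output_node=n_inputs + n_gates - 1
        )
        if len(circuit.input_ancestors()) == n_inputs:
            return circuit
    raise RuntimeError(
        "could not draw a circuit connecting every input; increase n_gates"
    )


def truth_table(circuit: BooleanCircuit) -> TruthTable:
    """Enumerate the full truth table under a uniform input distribution."""
    n = circuit.n_inputs
    if n > _MAX_ENUM_INPUTS:
        raise EnumerationTooLarge(f"2^{n} rows exceeds the enumeration guard")
    m = 2**n
    codes = np.arange(m, dtype=np.uint32)
    # x1 is the most significant bit
    inputs = ((codes[:, None] >> np.arange(n - 1, -1, -1)[None, :]) & 1).astype(np.uint8)
    outputs = circuit.evaluate(inputs)
    probs = np.full(m, 1.0 / m)
    return TruthTable(n_inputs=n, inputs=inputs, outputs=outputs, probs=probs)


def _conditional_output_entropy(table: TruthTable, subset: Sequence[int]) -> float:
    """H(Y | X_S) in bits, by exact marginalization of the row probabilities."""
    idx = np.asarray(sorted(subset), dtype=int)
    if idx.size == 0:
        return table.output_entropy()
    cols = table.inputs[:, idx].astype(np.int64)
    group = cols @ (1 << np.arange(idx.size - 1, -1, -1, dtype=np.int64))
    key = group * 2 + table.outputs
    n_groups = 1 << idx.size
    joint = np.bincount(key, weights=table.probs, minlength=2 * n_groups)
    joint = joint.reshape(n_groups, 2)
    px = joint.sum(axis=1)
    mask = joint > 0
    h = -(joint[mask] * np.log2(joint[mask] / px.repeat(2).reshape(n_groups, 2)[mask])).sum()
    return float(h)


def subset_information(table: TruthTable, subset: Iterable[int]) -> float:
    """Exact I(X_S; Y) in bits.  Subset indices are 1-based (x1..xN)."""
    subset = set(subset)
    if any(i < 1 or i > table.n_inputs for i in subset):
        raise ValueError(f"subset indices must lie in 1..{table.n_inputs}")
    zero_based = [i - 1 for i in subset]
    mi = table.output_entropy() - _conditional_output_entropy(table, zero_based)
    return max(mi, 0.0)


def subset_frontier(table: TruthTable):
    """I(X_S; Y) for every subset of inputs, plus the per-cardinality envelope.

    Returns ``(entries, envelope)`` where ``entries`` is a list of
    SubsetInformation over all 2^N subsets and ``envelope[k]`` is the
    maximum over subsets of size k (non-decreasing in k by monotonicity).
    """
    n = table.n_inputs
    if n > _MAX_FRONTIER_INPUTS:
        raise EnumerationTooLarge(f"2^{n} subsets exceeds the frontier guard")
    entries = []
    envelope = np.zeros(n + 1)
    for k in range(n + 1):
        for combo in combinations(range(1, n + 1), k):
            mi = subset_information(table, combo)
            entries.append(SubsetInformation(subset=frozenset(combo), mi_bits=mi))
            envelope[k] = max(envelope[k], mi)
    return entries, envelope
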