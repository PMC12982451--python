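"""Directed acyclic graph executor over layer ops.

Nodes are executed in declaration order (inputs must precede consumers).
Forward activations and backward gradients are retained per node so that
class-activation saliency can read both at any named tap point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from bosbench.nn.layers import Op, Param

INPUT = "input"


@dataclass
class Node:
    name: str
    op: Op
    inputs: list[str]


@dataclass
class Graph:
    nodes: list[Node]
    output: str
    activations: dict[str, np.ndarray] = field(default_factory=dict,
                                               repr=False)
    gradients: dict[str, np.ndarray] = field(default_factory=dict,
                                             repr=False)

    def __post_init__(self) -> None:
        names = {INPUT}
        for node in self.nodes:
            missing = [i for i in node.inputs if i not in names]
            if missing or node.name in names:
                raise ValueError(f"bad graph wiring at node {node.name!r}")
            names.add(node.name)
        if self.output not in names:
            raise ValueError(f"unknown output node {self.output!r}")

    def params(self) -> list[Param]:
        return [p for node in self.nodes for p in node.op.params()]

    def n_parameters(self) -> int:
        return int(sum(p.value.size for p in self.params()))

    def forward(self, x: np.ndarray, keep: bool = False) -> np.ndarray:
        """Run the graph; with ``keep`` the per-node activations survive."""
        x = np.asarray(x)
        if x.dtype != np.float64:
            x = x.astype(np.float32)
        vals: dict[str, np.ndarray] = {INPUT: x}
        for node in self.nodes:
            vals[node.name] = node.op.forward(*[vals[i] for i in node.inputs])
        self.activations = vals if keep else {}
        return vals[self.output]

    def backward(self, gout: np.ndarray, keep: bool = False) -> None:
        """Backpropagate ``gout`` (gradient at the output node).

        Parameter gradients accumulate into each op's ``Param.grad``; with
        ``keep`` the per-node activation gradients are retained in
        ``self.gradients``.
        """
        grads: dict[str, np.ndarray] = {self.output: gout}
        for node in reversed(self.nodes):
            g = grads.pop(node.name, None)
            if g is None:
                continue
            for iname, gin in zip(node.inputs, node.op.backward(g)):
                if iname in grads:
                    grads[iname] = grads[iname] + gin
                else:
                    grads[iname] = gin
                if keep:
                    self.gradients.setdefault(iname, np.zeros_like(gin))
            if keep:
                self.gradients[node.name] = g
        if keep:
            for iname, g in grads.items():
                self.gradients[iname] = g

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {}
        for node in self.nodes:
            for k, p in enumerate(node.op.params()):
                out[f"{node.name}.{k}"] = p.value
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for node in self.nodes:
            for k, p in enumerate(node.op.params()):
                p.value = np.asarray(state[f"{node.name}.{k}"],
                                     dtype=np.float32).reshape(p.value.shape)
                p.grad = np.zeros_like(p.value)
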