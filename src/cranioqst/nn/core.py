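"""Parameter and module primitives."""

from __future__ import annotations

import numpy as np


class Param:
    """A trainable array with its accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Module:
    """Base class: collects :class:`Param` objects from attributes recursively."""

    def params(self) -> list[Param]:
        out: list[Param] = []
        seen: set[int] = set()
        self._collect(out, seen)
        return out

    def _collect(self, out: list[Param], seen: set[int]) -> None:
        for value in vars(self).values():
            self._collect_value(value, out, seen)

    @staticmethod
    def _collect_value(value, out, seen) -> None:
        if isinstance(value, Param):
            if id(value) not in seen:
                seen.add(id(value))
                out.append(value)
        elif isinstance(value, Module):
            value._collect(out, seen)
        elif isinstance(value, (list, tuple)):
            for v in value:
                Module._collect_value(v, out, seen)
        elif isinstance(value, dict):
            for v in value.values():
                Module._collect_value(v, out, seen)

    def zero_grad(self) -> None:
        for p in self.params():
            p.zero_grad()

    def state_dict(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.params()]

    def load_state_dict(self, state: list[np.ndarray]) -> None:
        params = self.params()
        if len(state) != len(params):
            raise ValueError(f"state has {len(state)} arrays, model has {len(params)}")
        for p, v in zip(params, state):
            if p.value.shape != v.shape:
                raise ValueError(f"shape mismatch {p.value.shape} vs {v.shape}")
            p.value[...] = v
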