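"""Thin wrapper over scipy's HiGHS interface for building LPs and MILPs.

All optimisation in the package (task feasibility LPs, the tINIT selection
MILP, gap-filling MILPs) goes through :class:`LinearSystem`: a mutable
container of variables, ranged linear constraints and a linear objective,
solved with ``scipy.optimize.milp``.  Using one backend keeps tolerances and
determinism uniform.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import sparse
from scipy.optimize import LinearConstraint, milp, Bounds


class SolverError(RuntimeError):
    """Raised when the solver reports anything other than optimal/infeasible."""


@dataclass
class SolveResult:
    status: str                      # "optimal" | "infeasible"
    x: Optional[np.ndarray] = None
    objective: Optional[float] = None

    @property
    def feasible(self) -> bool:
        return self.status == "optimal"


@dataclass
class LinearSystem:
    """Incrementally built linear (mixed-integer) program, minimisation form."""

    names: List[str] = field(default_factory=list)
    lb: List[float] = field(default_factory=list)
    ub: List[float] = field(default_factory=list)
    obj: List[float] = field(default_factory=list)
    integer: List[bool] = field(default_factory=list)
    _rows: List[Tuple[List[int], List[float], float, float]] = field(default_factory=list)
    _index: Dict[str, int] = field(default_factory=dict)

    def add_var(
        self,
        name: str,
        lb: float = 0.0,
        ub: float = np.inf,
        obj: float = 0.0,
        integer: bool = False,
    ) -> int:
        if name in self._index:
            raise ValueError(f"duplicate variable {name!r}")
        idx = len(self.names)
        self.names.append(name)
        self.lb.append(float(lb))
        self.ub.append(float(ub))
        self.obj.append(float(obj))
        self.integer.append(integer)
        self._index[name] = idx
        return idx

    def var(self, name: str) -> int:
        return self._index[name]

    def has_var(self, name: str) -> bool:
        return name in self._index

    def set_objective(self, coeffs: Dict[int, float]) -> None:
        self.obj = [0.0] * len(self.names)
        for idx, c in coeffs.items():
            self.obj[idx] = float(c)

    def add_constraint(
        self,
        coeffs: Iterable[Tuple[int, float]],
        lb: float = -np.inf,
        ub: float = np.inf,
    ) -> None:
        idxs: List[int] = []
        vals: List[float] = []
        for i, v in coeffs:
            if v != 0.0:
                idxs.append(i)
                vals.append(float(v))
        self._rows.append((idxs, vals, float(lb), float(ub)))

    # -- solving -----------------------------------------------------------

    def solve(
        self,
        mip_gap: float = 1e-6,
        time_limit: Optional[float] = None,
    ) -> SolveResult:
        n = len(self.names)
        c = np.asarray(self.obj, dtype=float)
        constraints = []
        if self._rows:
            data, ri, ci, clo, cup = [], [], [], [], []
            for r, (idxs, vals, lo, up) in enumerate(self._rows):
                for i, v in zip(idxs, vals):
                    ri.append(r)
                    ci.append(i)
                    data.append(v)
                clo.append(lo)
                cup.append(up)
            A = sparse.csr_matrix(
                (data, (ri, ci)), shape=(len(self._rows), n)
            )
            constraints.append(LinearConstraint(A, np.asarray(clo), np.asarray(cup)))

        options: Dict[str, object] = {"mip_rel_gap": mip_gap, "presolve": True}
        if time_limit is not None:
            options["time_limit"] = time_limit
        res = milp(
            c=c,
            constraints=constraints,
            integrality=np.asarray(self.integer, dtype=int),
            bounds=Bounds(np.asarray(self.lb), np.asarray(self.ub)),
            options=options,
        )
        if res.status == 0:
            return SolveResult("optimal", x=res.x, objective=float(res.fun))
        if res.status == 2:
            return SolveResult("infeasible")
        raise SolverError(f"solver returned status {res.status}: {res.message}")

    def value(self, result: SolveResult, name: str) -> float:
        assert result.x is not None
        return float(result.x[self._index[name]])
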