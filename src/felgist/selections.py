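"""Tiny atom-selection language over the trajectory atom table.

Supported clauses, joined with ``and`` (optionally prefixed ``not``):

* ``resname GLC BGC`` — residue name membership
* ``resid 378`` / ``resid 10-20`` — residue id or inclusive range
* ``name CA C O N`` — atom-name membership
* ``chain A``
* ``element O``
* ``backbone`` / ``ligand`` / ``water`` / ``protein`` / ``heavy``

``protein`` means "not ligand and not water" (any non-solvent, non-ligand
atom), matching how the protein geometric center is defined.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .io_formats import AtomRecord

__all__ = ["Selection", "select"]


class SelectionError(ValueError):
    """Raised for unparsable expressions or empty required selections."""


_Clause = Callable[[AtomRecord], bool]


@dataclass(frozen=True)
class Selection:
    """A compiled selection; call :meth:`mask` or :meth:`indices` on atoms."""

    expression: str

    def mask(self, atoms: Sequence[AtomRecord]) -> np.ndarray:
        clauses = _parse(self.expression)
        out = np.ones(len(atoms), dtype=bool)
        for cl in clauses:
            out &= np.fromiter((cl(a) for a in atoms), bool, count=len(atoms))
        return out

    def indices(self, atoms: Sequence[AtomRecord]) -> np.ndarray:
        return np.flatnonzero(self.mask(atoms))

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.expression


def select(expression: str) -> Selection:
    _parse(expression)  # validate eagerly
    return Selection(expression)


def _is_water(a: AtomRecord) -> bool:
    from .constants import WATER_RESNAMES

    return a.residue_name.upper() in WATER_RESNAMES


_KEYWORDS: dict[str, _Clause] = {
    "backbone": lambda a: a.is_backbone,
    "ligand": lambda a: a.is_ligand,
    "water": _is_water,
    "protein": lambda a: not a.is_ligand and not _is_water(a),
    "heavy": lambda a: a.element.upper() != "H",
}


def _parse(expression: str) -> list[_Clause]:
    clauses: list[_Clause] = []
    for raw in expression.split(" and "):
        tokens = raw.split()
        if not tokens:
            raise SelectionError(f"empty clause in {expression!r}")
        negate = False
        if tokens[0] == "not":
            negate = True
            tokens = tokens[1:]
            if not tokens:
                raise SelectionError(f"dangling 'not' in {expression!r}")
        head, args = tokens[0].lower(), tokens[1:]
        if head in _KEYWORDS and not args:
            cl = _KEYWORDS[head]
        elif head == "resname" and args:
            names = {x.upper() for x in args}
            cl = lambda a, names=names: a.residue_name.upper() in names
        elif head == "name" and args:
            names = {x.upper() for x in args}
            cl = lambda a, names=names: a.name.upper() in names
        elif head == "chain" and args:
            chains = set(args)
            cl = lambda a, chains=chains: a.chain in chains
        elif head == "element" and args:
            els = {x.upper() for x in args}
            cl = lambda a, els=els: a.element.upper() in els
        elif head == "resid" and args:
            ids: set[int] = set()
            for tok in args:
                if "-" in tok[1:]:
                    lo, hi = tok.split("-", 1) if not tok.startswith("-") else (tok, tok)
                    ids.update(range(int(lo), int(hi) + 1))
                else:
                    ids.add(int(tok))
            cl = lambda a, ids=ids: a.residue_id in ids
        else:
            raise SelectionError(f"cannot parse clause {raw!r}")
        clauses.append((lambda a, cl=cl: not cl(a)) if negate else cl)
    return clauses
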