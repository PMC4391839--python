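"""RNA secondary-structure prediction backends.

Hairpin screening needs a single minimum-energy secondary structure in
dot-bracket form plus its MFE.  Two interchangeable backends are provided:

``BasePairEnergyBackend`` (default)
    An exact dynamic program over a simplified, stacking-free energy
    model: each base pair contributes a fixed energy (GC -3, AU -2,
    GU -1 kcal/mol), hairpin loops must enclose at least 3 unpaired
    bases, and pseudoknots are disallowed.  The optimum over all nested
    structures is found by a Nussinov-style recursion (numba-compiled);
    on sequences short enough to enumerate, it provably equals brute
    force.  Being self-contained, it is also the reference model the
    synthetic-data generator uses for planted-hairpin truth labels.

``ViennaBackend``
    Thin wrapper over the ViennaRNA thermodynamic nearest-neighbour
    model (37 degC parameters), when the ``RNA`` bindings are installed.

Note the two models' energy scales differ; screening thresholds such as
"MFE <= -20 kcal/mol" are calibrated to thermodynamic energies but remain
meaningful under the simplified model, where a canonical ~21-bp miRNA
stem scores far below -20 as well.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .seq_io import ValidationError, normalize_rna

try:  # pragma: no cover - exercised only where numba is present (always in CI)
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore
        def wrap(f):
            return f

        return wrap if not (args and callable(args[0])) else args[0]


MIN_HAIRPIN_LOOP = 3

# pair energies, kcal/mol per closed pair; 0 = cannot pair
_PAIR_ENERGY = np.zeros((4, 4), dtype=np.int64)
_PAIR_ENERGY[2, 1] = _PAIR_ENERGY[1, 2] = -3  # G:C
_PAIR_ENERGY[0, 3] = _PAIR_ENERGY[3, 0] = -2  # A:U
_PAIR_ENERGY[2, 3] = _PAIR_ENERGY[3, 2] = -1  # G:U

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "U": 3, "T": 3}


class FoldingError(RuntimeError):
    """A folding backend failed; carries the backend diagnostics."""


@dataclass(frozen=True)
class FoldResult:
    """Dot-bracket structure and its minimum free energy (kcal/mol)."""

    dotbracket: str
    mfe: float

    def __post_init__(self) -> None:
        depth = 0
        for ch in self.dotbracket:
            if ch == "(":
                depth += 1
            elif ch == ")":
                depth -= 1
                if depth < 0:
                    raise ValidationError("unbalanced dot-bracket")
            elif ch != ".":
                raise ValidationError(f"illegal structure character {ch!r}")
        if depth != 0:
            raise ValidationError("unbalanced dot-bracket")

    def pair_table(self) -> list[int]:
        """partner index per position, -1 if unpaired."""
        table = [-1] * len(self.dotbracket)
        stack: list[int] = []
        for i, ch in enumerate(self.dotbracket):
            if ch == "(":
                stack.append(i)
            elif ch == ")":
                j = stack.pop()
                table[i], table[j] = j, i
        return table


@njit(cache=True)
def _nussinov_matrix(codes, pair_energy, blocked, min_loop):  # pragma: no cover - numba
    n = codes.shape[0]
    e = np.zeros((n, n), dtype=np.int64)
    for span in range(min_loop + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = e[i, j - 1]  # j unpaired
            if not blocked[j]:
                for k in range(i, j - min_loop):
                    if blocked[k]:
                        continue
                    pe = pair_energy[codes[k], codes[j]]
                    if pe < 0:
                        cand = pe
                        if k > i:
                            cand += e[i, k - 1]
                        if k + 1 <= j - 1:
                            cand += e[k + 1, j - 1]
                        if cand < best:
                            best = cand
            e[i, j] = best
    return e


def _traceback(codes: np.ndarray, e: np.ndarray, blocked: np.ndarray, min_loop: int) -> str:
    n = len(codes)
    structure = ["."] * n
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if j - i <= min_loop:
            continue
        if e[i, j] == e[i, j - 1]:
            stack.append((i, j - 1))
            continue
        found = False
        for k in range(i, j - min_loop):
            if blocked[k] or blocked[j]:
                continue
            pe = _PAIR_ENERGY[codes[k], codes[j]]
            if pe >= 0:
                continue
            cand = pe
            if k > i:
                cand += e[i, k - 1]
            if k + 1 <= j - 1:
                cand += e[k + 1, j - 1]
            if cand == e[i, j]:
                structure[k], structure[j] = "(", ")"
                if k > i:
                    stack.append((i, k - 1))
                if k + 1 <= j - 1:
                    stack.append((k + 1, j - 1))
                found = True
                break
        if not found:  # pragma: no cover - defensive; recursion is exact
            raise FoldingError(f"traceback failed at span ({i}, {j})")
    return "".join(structure)


def _encode_rna(sequence: str) -> np.ndarray:
    seq = normalize_rna(sequence)
    if not seq:
        raise ValidationError("cannot fold an empty sequence")
    try:
        return np.array([_BASE_CODE[c] for c in seq], dtype=np.int64)
    except KeyError as exc:
        raise ValidationError(f"cannot fold sequence containing {exc.args[0]!r}") from None


class BasePairEnergyBackend:
    """Exact DP under the simplified per-pair energy model (see module docs)."""

    name = "basepair"

    def fold(self, sequence: str, blocked: np.ndarray | None = None) -> FoldResult:
        codes = _encode_rna(sequence)
        n = len(codes)
        if blocked is None:
            blocked = np.zeros(n, dtype=np.bool_)
        else:
            blocked = np.asarray(blocked, dtype=np.bool_)
            if blocked.shape[0] != n:
                raise ValidationError("constraint mask length != sequence length")
        if n <= MIN_HAIRPIN_LOOP + 1:
            return FoldResult("." * n, 0.0)
        e = _nussinov_matrix(codes, _PAIR_ENERGY, blocked, MIN_HAIRPIN_LOOP)
        db = _traceback(codes, e, blocked, MIN_HAIRPIN_LOOP)
        return FoldResult(db, float(e[0, n - 1]))


class ViennaBackend:
    """ViennaRNA thermodynamic MFE folding (requires the ``RNA`` bindings)."""

    name = "vienna"

    def __init__(self) -> None:
        try:
            import RNA  # noqa: F401
        except ImportError as exc:  # pragma: no cover
            raise FoldingError(
                "ViennaRNA python bindings not installed; use the default backend"
            ) from exc
        self._rna = RNA

    def fold(self, sequence: str, blocked: np.ndarray | None = None) -> FoldResult:
        seq = normalize_rna(sequence)
        if not seq:
            raise ValidationError("cannot fold an empty sequence")
        if blocked is not None and np.any(blocked):
            fc = self._rna.fold_compound(seq)
            for i in np.nonzero(np.asarray(blocked))[0]:
                fc.hc_add_up(int(i) + 1)  # 1-based
            db, mfe = fc.mfe()
        else:
            db, mfe = self._rna.fold(seq)
        return FoldResult(db, float(mfe))


_DEFAULT_BACKEND = BasePairEnergyBackend()


def fold(sequence: str, backend=None) -> FoldResult:
    """Fold an RNA sequence into its single minimum-energy structure.

    ``backend`` defaults to the self-contained base-pair-energy model.
    The sequence must be N-free.
    """
    backend = backend or _DEFAULT_BACKEND
    return backend.fold(sequence)


def fold_constrained(sequence: str, blocked, backend=None) -> FoldResult:
    """Fold with the positions flagged in ``blocked`` forced unpaired."""
    backend = backend or _DEFAULT_BACKEND
    return backend.fold(sequence, blocked=np.asarray(blocked, dtype=bool))
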