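"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import mirscan
from mirscan.folding import _PAIR_ENERGY, MIN_HAIRPIN_LOOP

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def catalogue():
    """The packaged 32-entry banana miRNA catalogue (known-length-discrepancy
    warning silenced; its presence is asserted in its own test)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return mirscan.load_catalogue()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


# ---------------------------------------------------------------- oracles

_CODE = {"A": 0, "C": 1, "G": 2, "U": 3, "T": 3}


def pair_energy_of(a: str, b: str) -> int:
    """Energy of one base pair under the simplified model (0 = cannot pair)."""
    return int(_PAIR_ENERGY[_CODE[a], _CODE[b]])


def enumerate_best_energy(seq: str, blocked: tuple[int, ...] = ()) -> int:
    """Exhaustive-recursion optimum energy over all nested structures.

    Independent of the DP implementation: plain recursion over 'leftmost
    base unpaired or paired to each legal partner', practical for
    sequences up to ~16 nt.
    """
    seq = seq.upper().replace("T", "U")

    def best(i: int, j: int) -> int:
        if j - i < MIN_HAIRPIN_LOOP + 1:
            return 0
        out = best(i + 1, j)
        if i not in blocked:
            for k in range(i + MIN_HAIRPIN_LOOP + 1, j + 1):
                if k in blocked:
                    continue
                e = pair_energy_of(seq[i], seq[k])
                if e < 0:
                    out = min(out, e + best(i + 1, k - 1) + best(k + 1, j))
        return out

    return best(0, len(seq) - 1)


def structure_energy(seq: str, dotbracket: str) -> int:
    """Score a dot-bracket structure by summing its pair energies."""
    seq = seq.upper().replace("T", "U")
    stack, total = [], 0
    for i, ch in enumerate(dotbracket):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            j = stack.pop()
            e = pair_energy_of(seq[j], seq[i])
            assert e < 0, f"non-pairable bases {seq[j]}{seq[i]} paired"
            assert i - j > MIN_HAIRPIN_LOOP, "hairpin loop below minimum"
            total += e
    assert not stack
    return total


def sliding_window_mismatches(ref: str, subject: str) -> list[tuple[int, int]]:
    """Brute-force (offset, mismatches) for every window, forward strand.

    Plain positional loop after U/T upper-casing; N counts as mismatching
    everything.  Windows containing N are reported like any other (the
    scanner's N-exclusion is asserted separately).
    """
    ref = ref.upper().replace("T", "U")
    subject = subject.upper().replace("T", "U")
    out = []
    for start in range(len(subject) - len(ref) + 1):
        mm = 0
        for a, b in zip(ref, subject[start : start + len(ref)]):
            if a != b or a == "N":
                mm += 1
        out.append((start, mm))
    return out
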