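"""Elastic (forced-bending) deformation energy of a nucleosome placement.

The nucleosome is modelled as a rod of dinucleotide-step segments with
step-specific roll/tilt stiffness, bent by a uniform torque ``F_b`` exerted
by the histone octamer.  The torque is calibrated so that the contacted
stretch of DNA (129 bp by default; roughly 9-10 bp at each end of the
147-bp core makes no histone contact) accumulates a fixed total bend angle
(579 degrees by default).  Twist is held constant at 34.8 degrees per step,
the crystallographic average for nucleosome-bound DNA, so the rotational
phase of step ``i`` relative to the dyad is fully determined by its index.

With :math:`\\Omega_i` the accumulated twist at the centre of step *i*
(steps are indexed ±1 … ±64 from the dyad; there is no step 0), the
equilibrium deviations under torque are

.. math::

    \\rho(i) - \\rho_0(i) = F_b \\cos\\Omega_i / k_\\rho(i), \\qquad
    \\tau(i) - \\tau_0(i) = F_b \\sin\\Omega_i / k_\\tau(i),

each step contributes

.. math::

    E_b(i) = \\frac{F_b^2}{2 k_\\rho(i)} \\cos^2\\Omega_i
           + \\frac{F_b^2}{2 k_\\tau(i)} \\sin^2\\Omega_i,

and the torque follows from the bend-angle constraint
:math:`\\alpha = \\sum_i \\rho(i)\\cos\\Omega_i + \\tau(i)\\sin\\Omega_i`:

.. math::

    F_b = \\frac{\\alpha - \\sum_i \\rho_0(i)\\cos\\Omega_i
                        - \\sum_i \\tau_0(i)\\sin\\Omega_i}
               {\\sum_i \\cos^2\\Omega_i/k_\\rho(i)
              + \\sum_i \\sin^2\\Omega_i/k_\\tau(i)}.

Energies are in the arbitrary units implied by the force constants, with
all angles in degrees; only relative energies matter downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np

__all__ = [
    "StepParams",
    "StepParamTable",
    "BendingGeometry",
    "PlacementEnergy",
    "EnergyModel",
    "build_param_table",
    "accumulated_twist",
    "torque",
    "placement_energy",
    "total_bend_angle",
    "reverse_complement",
    "encode_sequence",
]

_BASES = "ACGT"
_BASE_CODE = {b: i for i, b in enumerate(_BASES)}
_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

#: All 16 dinucleotide steps in lexicographic order; code = 4*first + second.
STEPS = tuple(a + b for a in _BASES for b in _BASES)


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (case preserved, IUPAC N kept as-is)."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode_sequence(seq: str) -> np.ndarray:
    """Encode bases as int8 codes A=0, C=1, G=2, T=3; anything else -> -1."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int8)
    for base, code in _BASE_CODE.items():
        out[arr == ord(base)] = code
    return out


@dataclass(frozen=True)
class StepParams:
    """Mechanical parameters of one dinucleotide step.

    k_rho, k_tau : force constants for roll and tilt deviation
        (energy per squared degree, arbitrary energy units).
    rho0, tau0 : equilibrium roll and tilt angles (degrees).
    """

    k_rho: float
    k_tau: float
    rho0: float
    tau0: float

    def __post_init__(self) -> None:
        if not (self.k_rho > 0 and self.k_tau > 0):
            raise ValueError(
                f"force constants must be positive, got k_rho={self.k_rho}, "
                f"k_tau={self.k_tau}"
            )


class StepParamTable:
    """Step-wise mechanical parameters for all 16 dinucleotide steps.

    The shipped parameter file lists one orientation per complementary
    pair (10 canonical rows).  Roll is invariant under strand reversal
    while tilt is antisymmetric, so the reverse-complement step shares
    ``k_rho``, ``k_tau`` and ``rho0`` but takes ``-tau0``.  Palindromic
    steps (AT, TA, GC, CG) therefore must have ``tau0 == 0``.
    """

    def __init__(self, entries: Mapping[str, StepParams]):
        entries = {k.upper(): v for k, v in entries.items()}
        missing = set(STEPS) - set(entries)
        if missing:
            raise ValueError(f"parameter table incomplete, missing steps: {sorted(missing)}")
        self._entries = {s: entries[s] for s in STEPS}
        self._validate_symmetry()
        # dense per-code arrays for vectorized energy evaluation
        self.k_rho = np.array([self._entries[s].k_rho for s in STEPS])
        self.k_tau = np.array([self._entries[s].k_tau for s in STEPS])
        self.rho0 = np.array([self._entries[s].rho0 for s in STEPS])
        self.tau0 = np.array([self._entries[s].tau0 for s in STEPS])

    def _validate_symmetry(self) -> None:
        for s in STEPS:
            rc = reverse_complement(s)
            a, b = self._entries[s], self._entries[rc]
            if not (
                math.isclose(a.k_rho, b.k_rho)
                and math.isclose(a.k_tau, b.k_tau)
                and math.isclose(a.rho0, b.rho0)
                and math.isclose(a.tau0, -b.tau0)
            ):
                raise ValueError(f"strand-symmetry violation between steps {s} and {rc}")

    def lookup(self, step: str) -> StepParams:
        try:
            return self._entries[step.upper()]
        except KeyError:
            raise KeyError(f"not a dinucleotide step: {step!r}") from None

    __getitem__ = lookup

    def items(self):
        return self._entries.items()

    @classmethod
    def from_tsv(cls, path: str | Path | None = None) -> "StepParamTable":
        """Load from a TSV with columns step, k_rho, k_tau, rho0, tau0.

        Rows may list either all 16 steps or one orientation per
        complementary pair; missing orientations are filled in by the
        strand-symmetry rule.  ``path=None`` loads the packaged defaults.
        """
        if path is None:
            src = resources.files("nucbend").joinpath("data/step_params.tsv")
            text = src.read_text()
        else:
            text = Path(path).read_text()
        entries: dict[str, StepParams] = {}
        lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
        header = lines[0].split("\t")
        expected = ["step", "k_rho", "k_tau", "rho0", "tau0"]
        if [h.strip() for h in header] != expected:
            raise ValueError(f"parameter file must have columns {expected}, got {header}")
        for ln in lines[1:]:
            fields = ln.split("\t")
            step = fields[0].strip().upper()
            k_rho, k_tau, rho0, tau0 = (float(x) for x in fields[1:5])
            entries[step] = StepParams(k_rho, k_tau, rho0, tau0)
        for step in list(entries):
            rc = reverse_complement(step)
            if rc not in entries:
                p = entries[step]
                entries[rc] = StepParams(p.k_rho, p.k_tau, p.rho0, -p.tau0)
        return cls(entries)


def build_param_table(path: str | Path | None = None) -> StepParamTable:
    """The default dinucleotide-step parameter table (all 16 steps)."""
    return StepParamTable.from_tsv(path)


@dataclass(frozen=True)
class BendingGeometry:
    """Geometry of the bent nucleosomal DNA.

    alpha_total : total bend angle of the contacted stretch (degrees).
    omega : uniform helical twist per dinucleotide step (degrees).
    core_len : nucleosome footprint (bp).
    contact_len : histone-contacted, sequence-scored stretch (bp); must be
        odd so a dyad base exists, and no longer than the footprint.
    """

    alpha_total: float = 579.0
    omega: float = 34.8
    core_len: int = 147
    contact_len: int = 129

    def __post_init__(self) -> None:
        if self.contact_len % 2 != 1:
            raise ValueError(f"contact_len must be odd, got {self.contact_len}")
        if self.contact_len > self.core_len:
            raise ValueError("contact_len may not exceed core_len")
        if self.contact_len < 3:
            raise ValueError("contact_len must be at least 3")
        if self.omega <= 0:
            raise ValueError("omega must be positive")

    @property
    def max_step_index(self) -> int:
        """Largest step index from the dyad: steps run i = ±1 … ±this."""
        return (self.contact_len - 1) // 2


@dataclass
class PlacementEnergy:
    """Deformation energy of one nucleosome placement.

    F_b is the calibrated torque; E_total the deformation energy summed
    over contacted steps; per_step, when retained, lists
    (step index i, accumulated twist Omega_i, E_b(i)) triples.
    Both are NaN for placements spanning ambiguous bases.
    """

    F_b: float
    E_total: float
    per_step: list[tuple[int, float, float]] | None = None


def accumulated_twist(i: int, omega: float) -> float:
    """Accumulated twist (degrees) at the centre of step ``i`` from the dyad.

    Step ±1 sits half a step from the dyad, so
    ``Omega_i = sign(i) * (0.5 + |i| - 1) * omega``; antisymmetric in i.
    """
    if i == 0:
        raise ValueError("there is no dinucleotide step with index 0")
    return math.copysign((0.5 + abs(i) - 1) * omega, i)


class EnergyModel:
    """Precomputed evaluation engine for one (table, geometry) pair.

    Builds, for each of the ``contact_len - 1`` step slots in the contacted
    window, per-step-code lookup rows for the three sums entering the
    torque and energy:

    * ``A = sum cos^2(Omega)/k_rho + sin^2(Omega)/k_tau``
    * ``B = sum rho0 * cos(Omega)``
    * ``C = sum tau0 * sin(Omega)``

    from which ``F_b = (alpha - B - C) / A`` and
    ``E_total = F_b^2 * A / 2``.

    A 17th column (code 16, reached by ambiguous bases) is NaN so that
    undefined placements propagate as missing rather than being imputed.
    """

    def __init__(self, table: StepParamTable | None = None, geom: BendingGeometry | None = None):
        self.table = table if table is not None else build_param_table()
        self.geom = geom if geom is not None else BendingGeometry()
        m = self.geom.max_step_index
        # slot d = -m .. m-1 holds the step whose first base is dyad+d;
        # its signed step index is d+1 for d >= 0, d for d < 0.
        self.offsets = np.arange(-m, m)
        self.step_indices = np.where(self.offsets >= 0, self.offsets + 1, self.offsets)
        omega_acc = np.sign(self.step_indices) * (np.abs(self.step_indices) - 0.5) * self.geom.omega
        self.omega_acc = omega_acc  # degrees, per slot
        rad = np.deg2rad(omega_acc)
        cos, sin = np.cos(rad), np.sin(rad)
        t = self.table
        nan_col = np.full((len(self.offsets), 1), np.nan)
        # rows: slot, cols: step code 0..15, plus NaN column for code 16
        self._a = np.hstack(
            [cos[:, None] ** 2 / t.k_rho[None, :] + sin[:, None] ** 2 / t.k_tau[None, :], nan_col]
        )
        self._b = np.hstack([cos[:, None] * t.rho0[None, :], nan_col])
        self._c = np.hstack([sin[:, None] * t.tau0[None, :], nan_col])
        self._cos = cos
        self._sin = sin

    # -- window-level API ---------------------------------------------------

    def _window_step_codes(self, window: str) -> np.ndarray:
        L = self.geom.contact_len
        if len(window) < L:
            raise ValueError(
                f"window of {len(window)} bp is shorter than contact_len={L}"
            )
        # centre the contacted stretch on the window midpoint (the dyad)
        centre = len(window) // 2
        if len(window) % 2 == 0:
            raise ValueError("window length must be odd so that a dyad base exists")
        sub = window[centre - L // 2 : centre + L // 2 + 1]
        codes = encode_sequence(sub)
        step_codes = np.where(
            (codes[:-1] >= 0) & (codes[1:] >= 0), codes[:-1] * 4 + codes[1:], 16
        )
        return step_codes

    def _sums(self, step_codes: np.ndarray) -> tuple[float, float, float]:
        idx = np.arange(len(step_codes))
        A = float(self._a[idx, step_codes].sum())
        B = float(self._b[idx, step_codes].sum())
        C = float(self._c[idx, step_codes].sum())
        return A, B, C

    def torque(self, window: str) -> float:
        """Calibrated torque F_b for the placement whose dyad is the window centre.

        NaN when the contacted stretch contains an ambiguous base.
        """
        A, B, C = self._sums(self._window_step_codes(window))
        return (self.geom.alpha_total - B - C) / A

    def placement_energy(self, window: str, keep_per_step: bool = False) -> PlacementEnergy:
        """Deformation energy of the placement centred on the window midpoint."""
        step_codes = self._window_step_codes(window)
        A, B, C = self._sums(step_codes)
        F_b = (self.geom.alpha_total - B - C) / A
        E_total = 0.5 * F_b * F_b * A
        per_step = None
        if keep_per_step:
            idx = np.arange(len(step_codes))
            e_steps = 0.5 * F_b * F_b * self._a[idx, step_codes]
            per_step = [
                (int(i), float(om), float(e))
                for i, om, e in zip(self.step_indices, self.omega_acc, e_steps)
            ]
        return PlacementEnergy(F_b=float(F_b), E_total=float(E_total), per_step=per_step)

    def total_bend_angle(self, window: str) -> float:
        """Total bend angle realised by the deformed roll/tilt profile.

        Deforms each step's roll and tilt under the placement's torque and
        sums their projections; by construction of the torque this returns
        ``geom.alpha_total`` for every unambiguous window (a conservation
        check, not new information).
        """
        step_codes = self._window_step_codes(window)
        A, B, C = self._sums(step_codes)
        F_b = (self.geom.alpha_total - B - C) / A
        t = self.table
        safe = np.minimum(step_codes, 15)
        undefined = step_codes == 16
        rho = t.rho0[safe] + F_b * self._cos / t.k_rho[safe]
        tau = t.tau0[safe] + F_b * self._sin / t.k_tau[safe]
        alpha = rho * self._cos + tau * self._sin
        alpha[undefined] = np.nan
        return float(alpha.sum())

    # -- sequence-level API -------------------------------------------------

    def sliding_energy(self, seq: str) -> np.ndarray:
        """Deformation energy at every dyad position of ``seq``.

        Returns an array of length ``len(seq)``; positions whose contacted
        stretch (dyad ± max_step_index) leaves the sequence, or spans an
        ambiguous base, are NaN.
        """
        N = len(seq)
        m = self.geom.max_step_index
        out = np.full(N, np.nan)
        if N < self.geom.contact_len:
            return out
        codes = encode_sequence(seq)
        step_codes = np.where(
            (codes[:-1] >= 0) & (codes[1:] >= 0), codes[:-1] * 4 + codes[1:], 16
        ).astype(np.intp)
        dyads = np.arange(m, N - m)
        A = np.zeros(len(dyads))
        B = np.zeros(len(dyads))
        C = np.zeros(len(dyads))
        for slot, d in enumerate(self.offsets):
            sc = step_codes[dyads + d]
            A += self._a[slot, sc]
            B += self._b[slot, sc]
            C += self._c[slot, sc]
        F_b = (self.geom.alpha_total - B - C) / A
        out[dyads] = 0.5 * F_b * F_b * A
        return out

    def sliding_torque(self, seq: str) -> np.ndarray:
        """Torque F_b at every dyad position (NaN where unscoreable)."""
        N = len(seq)
        m = self.geom.max_step_index
        out = np.full(N, np.nan)
        if N < self.geom.contact_len:
            return out
        codes = encode_sequence(seq)
        step_codes = np.where(
            (codes[:-1] >= 0) & (codes[1:] >= 0), codes[:-1] * 4 + codes[1:], 16
        ).astype(np.intp)
        dyads = np.arange(m, N - m)
        A = np.zeros(len(dyads))
        B = np.zeros(len(dyads))
        C = np.zeros(len(dyads))
        for slot, d in enumerate(self.offsets):
            sc = step_codes[dyads + d]
            A += self._a[slot, sc]
            B += self._b[slot, sc]
            C += self._c[slot, sc]
        out[dyads] = (self.geom.alpha_total - B - C) / A
        return out


# -- convenience module-level wrappers (build the engine per call) -----------

def torque(
    window: str,
    table: StepParamTable | None = None,
    geom: BendingGeometry | None = None,
) -> float:
    return EnergyModel(table, geom).torque(window)


def placement_energy(
    window: str,
    table: StepParamTable | None = None,
    geom: BendingGeometry | None = None,
    keep_per_step: bool = False,
) -> PlacementEnergy:
    return EnergyModel(table, geom).placement_energy(window, keep_per_step=keep_per_step)


def total_bend_angle(
    window: str,
    table: StepParamTable | None = None,
    geom: BendingGeometry | None = None,
) -> float:
    return EnergyModel(table, geom).total_bend_angle(window)
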