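"""Residue-level two-bead polymer topologies with sticker/lock annotations.

Each residue contributes a backbone bead and a side-chain bead.  Residues are
assigned one of four categories in the sticker–spacer sense: aromatic
``sticker`` residues carry the strongest pairwise attraction, hydrophobic
spacers a weaker one, polar spacers and flexible (glycine-like) residues are
nearly athermal.  An optional :class:`LockSpec` declares an antiparallel
pairing between two sequence segments whose backbone beads share a
pseudo-hydrogen-bond well — the intramolecular β-strand "lock" that holds
the chain closed at low temperature and melts on heating.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

CATEGORIES = ("sticker", "hydrophobic_spacer", "polar_spacer", "flexible")
CATEGORY_CODES = {name: i for i, name in enumerate(CATEGORIES)}

#: Categories whose pairwise attraction is scaled up with temperature
#: (solvent-entropy-driven LCST attraction made explicit).
STICKY_CATEGORIES = frozenset({"sticker", "hydrophobic_spacer"})

# Default side-chain attraction well depths per category, kJ/mol.  Calibrated
# once for the wild-type preset so the generator exhibits LCST compaction and
# a thermally breakable lock (see docs/methods.md).
DEFAULT_EPSILON = {
    "sticker": 2.8,
    "hydrophobic_spacer": 0.9,
    "polar_spacer": 0.25,
    "flexible": 0.15,
}

PRESET_NAMES = ("wt", "y_to_s", "m1", "m2", "no_lock_homopolymer")


@dataclass(frozen=True)
class ResidueSpec:
    """One residue of the coarse-grained chain."""

    index: int  # 1-based
    category: str
    sidechain_epsilon: float  # kJ/mol, >= 0
    label: str = ""

    def __post_init__(self):
        if self.index < 1:
            raise ValueError(f"residue index must be >= 1, got {self.index}")
        if self.category not in CATEGORY_CODES:
            raise ValueError(f"unknown residue category {self.category!r}")
        if self.sidechain_epsilon < 0:
            raise ValueError("sidechain_epsilon must be >= 0")


@dataclass(frozen=True)
class LockSpec:
    """Antiparallel two-segment β-strand lock.

    ``registry`` pairs residue indices of segment_a with segment_b in
    antiparallel order; each pair shares a Gaussian pseudo-H-bond well of
    depth ``epsilon_lock`` (kJ/mol) centred at ``r0`` (nm) with width
    ``width`` (nm), truncated at ``cutoff``.  The well depth weakens
    linearly on heating (``alpha_lock``): backbone hydrogen bonds compete
    with solvent, so their effective strength falls with temperature in an
    implicit-solvent model, which is what melts the lock while nonspecific
    sticker attraction is strengthening.
    """

    segment_a: tuple[int, int]  # inclusive 1-based range
    segment_b: tuple[int, int]
    registry: tuple[tuple[int, int], ...]
    #: per-rung well depth at the reference temperature (kJ/mol)
    epsilon_lock: float = 13.0
    #: cooperative bonus for adjacent intact rungs (kJ/mol); β-ladder
    #: hydrogen bonds are cooperative, and the product form keeps isolated
    #: crowding-induced near-contacts in a compact globule from counting
    #: as a lock.  Kept small so open/close kinetics stay fast.
    epsilon_coop: float = 1.5
    #: linear temperature coefficient of the well depth,
    #: ``eps(T) = eps * max(0, 1 - alpha_lock*(T - T_ref)/T_ref)`` — the
    #: implicit-solvent weakening of backbone hydrogen bonds on heating,
    #: mirroring the LCST strengthening of sticker contacts
    alpha_lock: float = 2.7
    r0: float = 0.32
    width: float = 0.12
    cutoff: float = 0.8
    #: each pair well is scaled by a smoothstep on the local backbone
    #: extension |b(i-1) - b(i+1)| of both partners, ramping from 0 at
    #: ``ext_lo`` to 1 at ``ext_hi`` (nm) — β-ladder bonds need extended
    #: strands
    ext_lo: float = 0.50
    ext_hi: float = 0.62

    def __post_init__(self):
        a0, a1 = self.segment_a
        b0, b1 = self.segment_b
        if a0 > a1 or b0 > b1:
            raise ValueError("segment ranges must be (lo, hi) with lo <= hi")
        if not (a1 < b0 or b1 < a0):
            raise ValueError("lock segments must be disjoint")
        if len(self.registry) < 2:
            raise ValueError("lock registry needs at least 2 pairs")
        if self.epsilon_lock < 0:
            raise ValueError("epsilon_lock must be >= 0")

    @staticmethod
    def antiparallel(segment_a: tuple[int, int], segment_b: tuple[int, int],
                     **kwargs) -> "LockSpec":
        """Build the canonical antiparallel registry between two equal-length
        segments: first residue of A pairs with last residue of B."""
        a = list(range(segment_a[0], segment_a[1] + 1))
        b = list(range(segment_b[1], segment_b[0] - 1, -1))
        if len(a) != len(b):
            raise ValueError("antiparallel lock segments must have equal length")
        return LockSpec(segment_a=tuple(segment_a), segment_b=tuple(segment_b),
                        registry=tuple(zip(a, b)), **kwargs)


@dataclass
class ChainTopology:
    """A one- or two-chain system of two-bead residues in a periodic cube.

    Bead layout: for chain ``c`` (0-based) and residue ``i`` (0-based within
    the chain), the backbone bead has index ``(c*n_res + i)*2`` and the
    side-chain bead ``(c*n_res + i)*2 + 1``.
    """

    residues: tuple[ResidueSpec, ...]
    backbone_bond_length: float = 0.38  # nm
    sidechain_bond_length: float = 0.25  # nm
    backbone_radius: float = 0.15  # nm, excluded-volume radius
    sidechain_radius: float = 0.20  # nm
    lock: Optional[LockSpec] = None
    n_chains: int = 1
    box_edge: float = 7.0  # nm, periodic cube
    #: 2 = backbone + side-chain bead (default); 1 = a single trace bead per
    #: residue, for small exactly-enumerable test systems
    beads_per_residue: int = 2

    def __post_init__(self):
        if len(self.residues) < 4:
            raise ValueError("chain length must be >= 4 residues")
        if self.n_chains not in (1, 2):
            raise ValueError("n_chains must be 1 or 2")
        if self.beads_per_residue not in (1, 2):
            raise ValueError("beads_per_residue must be 1 or 2")
        indices = [r.index for r in self.residues]
        if indices != list(range(1, len(self.residues) + 1)):
            raise ValueError("residues must be ordered with 1-based indices")
        if self.lock is not None:
            n = len(self.residues)
            for lo, hi in (self.lock.segment_a, self.lock.segment_b):
                if hi > n:
                    raise ValueError(
                        f"lock segment {lo}-{hi} exceeds chain length {n}")

    # ---- sizes -----------------------------------------------------------
    @property
    def n_residues(self) -> int:
        """Residues per chain."""
        return len(self.residues)

    @property
    def n_residues_total(self) -> int:
        return self.n_residues * self.n_chains

    @property
    def n_beads(self) -> int:
        return self.beads_per_residue * self.n_residues_total

    # ---- bead index helpers ---------------------------------------------
    def backbone_bead(self, residue_index: int, chain: int = 0) -> int:
        """Bead index of the backbone bead of a residue (1-based residue)."""
        return (chain * self.n_residues + residue_index - 1) * self.beads_per_residue

    def sidechain_bead(self, residue_index: int, chain: int = 0) -> int:
        if self.beads_per_residue == 1:
            return self.backbone_bead(residue_index, chain)
        return self.backbone_bead(residue_index, chain) + 1

    def bead_radii(self) -> np.ndarray:
        if self.beads_per_residue == 1:
            return np.full(self.n_beads, self.backbone_radius)
        r = np.empty(self.n_beads)
        r[0::2] = self.backbone_radius
        r[1::2] = self.sidechain_radius
        return r

    def bead_chain_ids(self) -> np.ndarray:
        ids = np.repeat(np.arange(self.n_chains),
                        self.beads_per_residue * self.n_residues)
        return ids

    def bead_residue_ids(self) -> np.ndarray:
        """Global 0-based residue id per bead (unique across chains)."""
        return np.repeat(np.arange(self.n_residues_total), self.beads_per_residue)

    def residue_epsilons(self) -> np.ndarray:
        """Per-residue side-chain epsilons, tiled over chains."""
        eps = np.array([r.sidechain_epsilon for r in self.residues])
        return np.tile(eps, self.n_chains)

    def residue_sticky(self) -> np.ndarray:
        sticky = np.array([r.category in STICKY_CATEGORIES for r in self.residues])
        return np.tile(sticky, self.n_chains)

    def to_dict(self) -> dict:
        d = {
            "residues": [asdict(r) for r in self.residues],
            "backbone_bond_length": self.backbone_bond_length,
            "sidechain_bond_length": self.sidechain_bond_length,
            "backbone_radius": self.backbone_radius,
            "sidechain_radius": self.sidechain_radius,
            "lock": asdict(self.lock) if self.lock is not None else None,
            "n_chains": self.n_chains,
            "box_edge": self.box_edge,
            "beads_per_residue": self.beads_per_residue,
        }
        return d

    @staticmethod
    def from_dict(d: dict) -> "ChainTopology":
        lock = d.get("lock")
        if lock is not None:
            lock = LockSpec(
                segment_a=tuple(lock["segment_a"]),
                segment_b=tuple(lock["segment_b"]),
                registry=tuple(tuple(p) for p in lock["registry"]),
                epsilon_lock=lock["epsilon_lock"],
                epsilon_coop=lock.get("epsilon_coop", 1.5),
                alpha_lock=lock.get("alpha_lock", 2.7),
                r0=lock["r0"], width=lock["width"], cutoff=lock["cutoff"],
                ext_lo=lock.get("ext_lo", 0.50), ext_hi=lock.get("ext_hi", 0.62),
            )
        residues = tuple(ResidueSpec(**r) for r in d["residues"])
        return ChainTopology(
            residues=residues,
            backbone_bond_length=d["backbone_bond_length"],
            sidechain_bond_length=d["sidechain_bond_length"],
            backbone_radius=d["backbone_radius"],
            sidechain_radius=d["sidechain_radius"],
            lock=lock,
            n_chains=d["n_chains"],
            box_edge=d["box_edge"],
            beads_per_residue=d.get("beads_per_residue", 2),
        )

    def digest(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()


# --------------------------------------------------------------------------
# Presets

LOCK_SEGMENT_A = (25, 30)
LOCK_SEGMENT_B = (77, 82)


# The lock segments are kept polar: their side-chain contacts then come
# almost entirely from the paired duplex, so melting the registry on heating
# shows up as a *loss* of contacts against the global sticker-driven gain —
# the Δcontact signature the analysis stage looks for.
_LOCK_SEGMENT_PATTERN = ("polar_spacer",) * 6


def _wt_residues(length: int) -> list[ResidueSpec]:
    """Aromatic/hydrophobic-rich sticker–spacer chain.

    Stickers sit on every third residue with hydrophobic spacers between
    (the domain is enriched in aromatic and hydrophobic residues); the rest
    are polar, with a short flexible hinge midway and polar lock segments.
    """
    cats = {}
    for seg in (LOCK_SEGMENT_A, LOCK_SEGMENT_B):
        if seg[1] <= length:
            for k, i in enumerate(range(seg[0], seg[1] + 1)):
                cats[i] = _LOCK_SEGMENT_PATTERN[k % len(_LOCK_SEGMENT_PATTERN)]
            # polar flanks: without them, sticker neighbours compete the
            # duplex open a few kelvin earlier in the wild type than in the
            # sticker-weakened variant, which muddies preset comparisons in
            # the melt region
            for i in range(max(1, seg[0] - 3), seg[0]):
                cats[i] = "polar_spacer"
            for i in range(seg[1] + 1, min(length, seg[1] + 3) + 1):
                cats[i] = "polar_spacer"
    residues = []
    label_letter = {"sticker": "Y", "hydrophobic_spacer": "L",
                    "polar_spacer": "S", "flexible": "G"}
    for i in range(1, length + 1):
        if i in cats:
            cat = cats[i]
        elif 50 <= i <= 55:
            cat = "flexible"
        elif i % 3 == 1:
            cat = "sticker"
        elif i % 3 == 0:
            cat = "hydrophobic_spacer"
        else:
            cat = "polar_spacer"
        residues.append(ResidueSpec(index=i, category=cat,
                                    sidechain_epsilon=DEFAULT_EPSILON[cat],
                                    label=f"{label_letter[cat]}{i}"))
    return residues


def build_preset(name: str, length: int = 90, **topology_kwargs) -> ChainTopology:
    """Build one of the named chain presets.

    Parameters
    ----------
    name:
        ``wt`` — stickers + antiparallel lock between residues 25–30 and
        77–82; ``y_to_s`` — sticker attractions reduced to polar-spacer
        level, lock retained; ``m1``/``m2`` — lock well depth zeroed
        (segment-a / segment-b mutants), stickers retained;
        ``no_lock_homopolymer`` — uniform polar spacers, no lock.
    length:
        residues per chain; presets referencing the 25–30/77–82 lock
        require ``length >= 84``.
    """
    if name not in PRESET_NAMES:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")

    needs_lock = name in ("wt", "y_to_s", "m1", "m2")
    if needs_lock and length < LOCK_SEGMENT_B[1] + 2:
        raise ValueError(
            f"preset {name!r} needs length >= {LOCK_SEGMENT_B[1] + 2} to hold "
            f"the {LOCK_SEGMENT_A}/{LOCK_SEGMENT_B} lock segments")

    if name == "no_lock_homopolymer":
        residues = tuple(
            ResidueSpec(index=i, category="polar_spacer",
                        sidechain_epsilon=DEFAULT_EPSILON["polar_spacer"],
                        label=f"S{i}")
            for i in range(1, length + 1))
        return ChainTopology(residues=residues, lock=None, **topology_kwargs)

    residues = _wt_residues(length)
    lock = LockSpec.antiparallel(LOCK_SEGMENT_A, LOCK_SEGMENT_B)

    if name == "y_to_s":
        residues = [
            ResidueSpec(index=r.index, category=r.category,
                        sidechain_epsilon=DEFAULT_EPSILON["polar_spacer"],
                        label=r.label.replace("Y", "S"))
            if r.category == "sticker" else r
            for r in residues
        ]
    elif name in ("m1", "m2"):
        # Alanine substitutions in one lock segment abolish the pairing
        # energy; stickers elsewhere are untouched.
        lock = LockSpec.antiparallel(LOCK_SEGMENT_A, LOCK_SEGMENT_B,
                                     epsilon_lock=0.0, epsilon_coop=0.0)

    return ChainTopology(residues=tuple(residues), lock=lock, **topology_kwargs)
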