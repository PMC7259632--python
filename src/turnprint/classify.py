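"""Composite epitope-presentation classification for aggregate structures.

A chain presents the epitope when its turn window is sharp, its key lysine
side chain is solvent-exposed in the context of the whole aggregate, that
lysine is not sequestered in a salt bridge with a configured carboxylate
partner, and the turn is not crowded by equivalent turns of neighboring
chains. The aggregate verdict is positive when at least ``min_chains``
chains pass all criteria. The conjunction rule is one defensible
formalization of a narrative decision process; every criterion is
configurable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import SelectionError
from .fingerprint import ANIONIC_SIDECHAINS, CATIONIC_SIDECHAINS
from .geometry import (DEFAULT_SHARP_MAX, DEFAULT_WIDE_MAX, SasaResult,
                       shrake_rupley_sasa, sidechain_sasa, turn_span, TurnSpan)
from .structure import Residue, Structure

__all__ = ["EpitopeDefinition", "ClassifierConfig", "ChainAssessment",
           "AggregateVerdict", "assess_chain", "classify_aggregate"]


@dataclass(frozen=True)
class EpitopeDefinition:
    """The turn window, key residue and salt-bridge partner set."""

    start_res: int = 25
    end_res: int = 29
    key_residue: int = 28
    key_partner_res: tuple[int, ...] = (23,)
    include_cterm_partner: bool = True

    def __post_init__(self) -> None:
        if not self.start_res < self.end_res:
            raise ValueError("start_res must be below end_res")
        if not (self.start_res <= self.key_residue <= self.end_res):
            raise ValueError("key_residue must lie inside the turn window")


@dataclass(frozen=True)
class ClassifierConfig:
    sharp_max: float = DEFAULT_SHARP_MAX
    wide_max: float = DEFAULT_WIDE_MAX
    exposure_threshold: float = 20.0   # Å² of key-residue side-chain SASA
    clearance: float = 10.0            # Å between equivalent turn centroids
    bridge_cutoff: float = 6.0         # ionic cutoff for the salt-bridge screen
    min_chains: int = 1
    sasa_probe: float = 1.4
    sasa_points: int = 960


@dataclass
class ChainAssessment:
    chain_id: str
    evaluable: bool
    turn: TurnSpan | None = None
    key_sasa: float | None = None
    key_exposed: bool | None = None
    key_salt_bridged: bool | None = None
    bridge_partners: list[tuple[str, int, str]] = field(default_factory=list)
    crowding_distance: float = math.inf
    accessible: bool | None = None
    reason: str = ""

    @property
    def passes(self) -> bool:
        return bool(self.evaluable
                    and self.turn is not None and self.turn.turn_class == "sharp"
                    and self.key_exposed
                    and not self.key_salt_bridged
                    and self.accessible)

    def criteria_trace(self) -> dict[str, bool | None]:
        return {
            "sharp_turn": None if self.turn is None else self.turn.turn_class == "sharp",
            "key_exposed": self.key_exposed,
            "key_not_bridged": None if self.key_salt_bridged is None
            else not self.key_salt_bridged,
            "accessible": self.accessible,
        }


@dataclass
class AggregateVerdict:
    assessments: list[ChainAssessment]
    positive: bool
    evaluable: bool
    supporting_chains: list[str]
    min_chains: int


def _turn_centroid(structure: Structure, chain: str,
                   epitope: EpitopeDefinition) -> np.ndarray | None:
    coords = []
    for res_seq in range(epitope.start_res, epitope.end_res + 1):
        residue = structure.get_residue(chain, res_seq)
        if residue is None:
            continue
        ca = residue.atom("CA")
        if ca is not None:
            coords.append(ca.coord)
    if not coords:
        return None
    return np.mean(coords, axis=0)


def _cation_coords(residue: Residue) -> np.ndarray | None:
    names = CATIONIC_SIDECHAINS.get(residue.res_name)
    if not names:
        return None
    coords = [residue.atom(n).coord for n in names if residue.atom(n) is not None]
    return np.array(coords) if coords else None


def _partner_carboxylates(structure: Structure, epitope: EpitopeDefinition
                          ) -> list[tuple[tuple[str, int, str], np.ndarray]]:
    """Carboxylate-oxygen coordinate sets of all configured partners, from
    every chain (intra- and inter-chain screening)."""
    out = []
    for residue in structure.residues:
        if residue.res_seq in epitope.key_partner_res:
            names = ANIONIC_SIDECHAINS.get(residue.res_name)
            if names:
                coords = [residue.atom(n).coord for n in names
                          if residue.atom(n) is not None]
                if coords:
                    out.append((residue.key, np.array(coords)))
    if epitope.include_cterm_partner:
        for residues in structure.chains.values():
            last = residues[-1]
            coords = [last.atom(n).coord for n in ("O", "OXT")
                      if last.atom(n) is not None]
            if coords:
                out.append((last.key, np.array(coords)))
    return out


def assess_chain(structure: Structure, chain: str,
                 epitope: EpitopeDefinition = EpitopeDefinition(),
                 config: ClassifierConfig = ClassifierConfig(),
                 sasa: SasaResult | None = None) -> ChainAssessment:
    """Evaluate the three positivity criteria for one chain.

    ``sasa`` may be a precomputed whole-aggregate SASA to avoid repeating
    the dominant cost across chains. Missing epitope residues make the
    chain not-evaluable rather than raising.
    """
    key_res = structure.get_residue(chain, epitope.key_residue)
    try:
        turn = turn_span(structure, chain, epitope.start_res, epitope.end_res,
                         config.sharp_max, config.wide_max)
    except SelectionError as exc:
        return ChainAssessment(chain_id=chain, evaluable=False, reason=str(exc))
    if key_res is None:
        return ChainAssessment(chain_id=chain, evaluable=False,
                               reason=f"key residue {epitope.key_residue} absent")

    if sasa is None:
        sasa = shrake_rupley_sasa(structure, probe=config.sasa_probe,
                                  n_points=config.sasa_points)
    key_sasa = sidechain_sasa(sasa, key_res)
    exposed = key_sasa >= config.exposure_threshold

    bridged = False
    partners: list[tuple[str, int, str]] = []
    cation = _cation_coords(key_res)
    if cation is not None:
        for partner_key, carboxylate in _partner_carboxylates(structure, epitope):
            if partner_key == key_res.key:
                continue
            d = np.sqrt(((cation[:, None, :] - carboxylate[None, :, :]) ** 2).sum(axis=2))
            if float(d.min()) <= config.bridge_cutoff:
                bridged = True
                partners.append(partner_key)

    own_centroid = _turn_centroid(structure, chain, epitope)
    crowding = math.inf
    for other in structure.chain_ids:
        if other == chain:
            continue
        centroid = _turn_centroid(structure, other, epitope)
        if centroid is None or own_centroid is None:
            continue
        crowding = min(crowding, float(np.linalg.norm(own_centroid - centroid)))
    accessible = crowding >= config.clearance

    return ChainAssessment(chain_id=chain, evaluable=True, turn=turn,
                           key_sasa=key_sasa, key_exposed=exposed,
                           key_salt_bridged=bridged, bridge_partners=partners,
                           crowding_distance=crowding, accessible=accessible)


def classify_aggregate(structure: Structure,
                       epitope: EpitopeDefinition = EpitopeDefinition(),
                       config: ClassifierConfig = ClassifierConfig()
                       ) -> AggregateVerdict:
    """Per-chain assessments plus the aggregate positive/negative call."""
    if not structure.residues:
        raise ValueError("structure has no chains")
    sasa = shrake_rupley_sasa(structure, probe=config.sasa_probe,
                              n_points=config.sasa_points)
    assessments = [assess_chain(structure, chain, epitope, config, sasa=sasa)
                   for chain in structure.chain_ids]
    evaluable = any(a.evaluable for a in assessments)
    supporting = [a.chain_id for a in assessments if a.passes]
    positive = evaluable and len(supporting) >= config.min_chains
    return AggregateVerdict(assessments=assessments, positive=positive,
                            evaluable=evaluable, supporting_chains=supporting,
                            min_chains=config.min_chains)
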