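"""Functional-residue fingerprinting and rhodopsin class calling.

Microbial rhodopsins fall into functional classes distinguishable by the
residues at a handful of anchored positions: the Schiff-base proton acceptor
and donor in Helix C (Asp98/Asp109 in precursor-numbered bacteriorhodopsin),
the retinal-binding lysine, a diagnostic Helix-G column, and the
retinal-binding pocket.  Proton pumps carry Asp at both Helix-C positions;
chloride pumps carry the Thr/Ala configuration; sensory rhodopsins lack the
donor Asp; xenorhodopsins additionally carry a conserved Pro at the Helix-G
column where every other class keeps Asp.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import pandas as pd
import yaml

from .align import (
    UNALIGNED,
    PositionMap,
    ScoringScheme,
    aligned_fraction,
    map_positions,
    residue_at,
)
from .seqio import ProteinRecord, read_fasta


class RhodopsinClass(str, Enum):
    PROTON_PUMP = "PROTON_PUMP"
    CHLORIDE_PUMP = "CHLORIDE_PUMP"
    SENSORY = "SENSORY"
    XENORHODOPSIN = "XENORHODOPSIN"
    UNCLASSIFIED = "UNCLASSIFIED"


@dataclass(frozen=True)
class FingerprintConfig:
    """Anchored positions (reference precursor numbering) and rule thresholds."""

    acceptor_pos: int = 98
    donor_pos: int = 109
    schiff_lysine_pos: int = 229
    helixG_diag_pos: int = 225
    inward_pump_pos: int = 230
    pocket_positions: dict[int, frozenset[str]] = field(default_factory=dict)
    pocket_min_fraction: float = 0.8
    min_aligned_fraction: float = 0.5
    numbering_offset: int = 13

    def __post_init__(self) -> None:
        named = [
            self.acceptor_pos,
            self.donor_pos,
            self.schiff_lysine_pos,
            self.helixG_diag_pos,
        ]
        if len(set(named)) != len(named):
            raise ValueError("fingerprint positions must be distinct")
        if not 0.0 <= self.pocket_min_fraction <= 1.0:
            raise ValueError("pocket_min_fraction must be in [0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FingerprintConfig":
        with Path(path).open() as fh:
            raw = yaml.safe_load(fh)
        pocket = {
            int(pos): frozenset(res) for pos, res in raw.pop("pocket_positions", {}).items()
        }
        return cls(pocket_positions=pocket, **raw)


def default_config() -> FingerprintConfig:
    """The packaged fingerprint configuration."""
    ref = importlib.resources.files("xenoscan") / "data" / "fingerprint.yaml"
    with importlib.resources.as_file(ref) as path:
        return FingerprintConfig.from_yaml(path)


def load_reference() -> ProteinRecord:
    """The packaged anchor protein (mature bacteriorhodopsin)."""
    ref = importlib.resources.files("xenoscan") / "data" / "bacteriorhodopsin.fasta"
    with importlib.resources.as_file(ref) as path:
        return read_fasta(path, "protein")[0]


@dataclass(frozen=True)
class ResidueFingerprint:
    """Residues observed at the anchored functional positions of one protein."""

    query_id: str
    acceptor: str
    donor: str
    schiff_lysine: str
    helixG: str
    inward_pump_site: str
    pocket_residues: dict[int, str]
    pocket_match_fraction: float
    low_confidence: bool = False


@dataclass(frozen=True)
class ClassCall:
    """A class label plus the ordered rule evidence that produced it."""

    label: RhodopsinClass
    evidence: tuple[tuple[str, str, str, bool], ...]  # (rule, observed, expected, passed)

    def __post_init__(self) -> None:
        if not self.evidence:
            raise ValueError("class call must carry evidence")


def extract_fingerprint(
    query: ProteinRecord,
    cfg: FingerprintConfig | None = None,
    reference: ProteinRecord | None = None,
    scheme: ScoringScheme = ScoringScheme(),
) -> ResidueFingerprint:
    """Read the anchored functional residues off ``query``.

    The query is globally aligned to the reference; residues are read through
    the resulting position map.  A query covering less than
    ``cfg.min_aligned_fraction`` of the reference is flagged low-confidence.
    """
    cfg = cfg or default_config()
    reference = reference or load_reference()
    pmap: PositionMap = map_positions(query, reference, cfg.numbering_offset, scheme)
    pocket = {p: residue_at(pmap, query, p) for p in sorted(cfg.pocket_positions)}
    matched = sum(
        1 for p, res in pocket.items() if res in cfg.pocket_positions[p]
    )
    frac = matched / len(cfg.pocket_positions) if cfg.pocket_positions else 1.0
    return ResidueFingerprint(
        query_id=query.id,
        acceptor=residue_at(pmap, query, cfg.acceptor_pos),
        donor=residue_at(pmap, query, cfg.donor_pos),
        schiff_lysine=residue_at(pmap, query, cfg.schiff_lysine_pos),
        helixG=residue_at(pmap, query, cfg.helixG_diag_pos),
        inward_pump_site=residue_at(pmap, query, cfg.inward_pump_pos),
        pocket_residues=pocket,
        pocket_match_fraction=frac,
        low_confidence=aligned_fraction(pmap, reference) < cfg.min_aligned_fraction,
    )


def classify(fp: ResidueFingerprint, cfg: FingerprintConfig | None = None) -> ClassCall:
    """Assign a functional class from a fingerprint (pure function).

    Rule precedence:

    1. no Schiff-base Lys, pocket match below threshold, or low-confidence
       anchoring -> UNCLASSIFIED (retinal binding not supported);
    2. acceptor Asp and donor Asp -> PROTON_PUMP;
    3. acceptor Thr and donor Ala -> CHLORIDE_PUMP;
    4. donor not Asp and Helix-G diagnostic Pro -> XENORHODOPSIN;
    5. donor not Asp otherwise -> SENSORY;
    6. anything else -> UNCLASSIFIED.
    """
    cfg = cfg or default_config()
    evidence: list[tuple[str, str, str, bool]] = []

    lys_ok = fp.schiff_lysine == "K"
    pocket_ok = fp.pocket_match_fraction >= cfg.pocket_min_fraction
    anchored_ok = not fp.low_confidence
    evidence.append(("schiff_lysine", fp.schiff_lysine, "K", lys_ok))
    evidence.append(
        (
            "pocket_match",
            f"{fp.pocket_match_fraction:.2f}",
            f">={cfg.pocket_min_fraction:.2f}",
            pocket_ok,
        )
    )
    evidence.append(("anchoring", "low" if fp.low_confidence else "ok", "ok", anchored_ok))
    if not (lys_ok and pocket_ok and anchored_ok):
        return ClassCall(RhodopsinClass.UNCLASSIFIED, tuple(evidence))

    proton = fp.acceptor == "D" and fp.donor == "D"
    evidence.append(("proton_pump_DD", f"{fp.acceptor}/{fp.donor}", "D/D", proton))
    if proton:
        return ClassCall(RhodopsinClass.PROTON_PUMP, tuple(evidence))

    chloride = fp.acceptor == "T" and fp.donor == "A"
    evidence.append(("chloride_pump_TA", f"{fp.acceptor}/{fp.donor}", "T/A", chloride))
    if chloride:
        return ClassCall(RhodopsinClass.CHLORIDE_PUMP, tuple(evidence))

    donor_non_asp = fp.donor != "D" and fp.donor != UNALIGNED
    xeno = donor_non_asp and fp.helixG == "P"
    evidence.append(("xeno_helixG_pro", fp.helixG, "P (with donor != D)", xeno))
    if xeno:
        return ClassCall(RhodopsinClass.XENORHODOPSIN, tuple(evidence))
    evidence.append(("sensory_donor_non_asp", fp.donor, "!= D", donor_non_asp))
    if donor_non_asp:
        return ClassCall(RhodopsinClass.SENSORY, tuple(evidence))
    return ClassCall(RhodopsinClass.UNCLASSIFIED, tuple(evidence))


def batch_classify(
    records: list[ProteinRecord],
    cfg: FingerprintConfig | None = None,
    reference: ProteinRecord | None = None,
    scheme: ScoringScheme = ScoringScheme(),
) -> pd.DataFrame:
    """Fingerprint and classify every record; one row per input, order kept.

    Per-record failures are recorded in the ``error`` column and never abort
    the batch.
    """
    if not records:
        raise ValueError("batch_classify requires a non-empty input")
    cfg = cfg or default_config()
    reference = reference or load_reference()
    rows = []
    for rec in records:
        row: dict = {"id": rec.id}
        try:
            fp = extract_fingerprint(rec, cfg, reference, scheme)
            call = classify(fp, cfg)
            row.update(
                acceptor=fp.acceptor,
                donor=fp.donor,
                schiff_lysine=fp.schiff_lysine,
                helixG=fp.helixG,
                inward_pump_site=fp.inward_pump_site,
                pocket_fraction=round(fp.pocket_match_fraction, 3),
                low_confidence=fp.low_confidence,
                label=call.label.value,
                evidence="; ".join(
                    f"{rule}:{obs}~{exp}:{'pass' if ok else 'fail'}"
                    for rule, obs, exp, ok in call.evidence
                ),
                error="",
            )
        except Exception as exc:  # noqa: BLE001 -- contract: batch never aborts
            row.update(label=RhodopsinClass.UNCLASSIFIED.value, error=str(exc))
        rows.append(row)
    return pd.DataFrame(rows)
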