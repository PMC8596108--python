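"""Data model, file readers/writers and run configuration.

All concentrations are stored internally in molar units.  Tables are
long/tidy CSV or TSV files (well geometry is never used by the analysis,
so a plate-position column is at most optional metadata).  Formatting of
concentrations for display picks µM or nM by magnitude.
"""

from __future__ import annotations

import dataclasses
import enum
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Role",
    "Outcome",
    "DrugPanelEntry",
    "PlateWell",
    "TreatmentRecord",
    "SurvivalRecord",
    "RunConfig",
    "FormatError",
    "ValidationError",
    "dilution_series",
    "format_conc",
    "default_panel",
    "MICROTUBULE_DRUGS",
    "read_plate_table",
    "write_plate_table",
    "read_panel",
    "write_panel",
    "read_treatments",
    "write_treatments",
    "read_survival",
    "write_survival",
    "write_table",
    "read_table",
]


class FormatError(ValueError):
    """A file is structurally malformed (e.g. a required column is missing)."""


class ValidationError(ValueError):
    """A record violates a domain invariant (e.g. negative signal)."""


class Role(str, enum.Enum):
    """Role of a well on a screening plate."""

    TEST = "test"
    NEG_CONTROL = "neg_control"
    POS_CONTROL = "pos_control"


class Outcome(str, enum.Enum):
    """RECIST response categories, plus an explicit unknown."""

    CR = "CR"
    PR = "PR"
    SD = "SD"
    PD = "PD"
    UNKNOWN = "unknown"


#: treatments with CR, PR or SD count as a good clinical response;
#: PD is a poor response; unknown outcomes are excluded from metrics.
GOOD_OUTCOMES = frozenset({Outcome.CR, Outcome.PR, Outcome.SD})


@dataclass(frozen=True)
class DrugPanelEntry:
    """One drug of the screening panel with its tested dilution range.

    ``top_conc`` is the highest tested concentration in molar; the series
    descends by ``fold`` for ``n_points`` doses (default: 20 µM top,
    threefold, 7 points — so the lowest dose is 27.4 nM).
    """

    drug_id: str
    target_label: str = ""
    top_conc: float = 20e-6
    fold: float = 3.0
    n_points: int = 7
    approved_for_breast: bool = False

    def __post_init__(self) -> None:
        if not self.drug_id:
            raise ValidationError("drug_id must be non-empty")
        if not self.top_conc > 0:
            raise ValidationError(f"top_conc must be > 0, got {self.top_conc}")
        if not self.fold > 1:
            raise ValidationError(f"fold must be > 1, got {self.fold}")
        if self.n_points < 1:
            raise ValidationError(f"n_points must be >= 1, got {self.n_points}")

    @property
    def concentrations(self) -> np.ndarray:
        return dilution_series(self.top_conc, self.fold, self.n_points)

    @property
    def min_conc(self) -> float:
        return float(self.top_conc / self.fold ** (self.n_points - 1))


@dataclass(frozen=True)
class PlateWell:
    """A single well read: raw luminescence plus its role on the plate."""

    pdo_id: str
    drug_id: str
    conc: float
    replicate: int
    raw_signal: float
    role: Role

    def __post_init__(self) -> None:
        object.__setattr__(self, "role", Role(self.role))
        if self.raw_signal < 0:
            raise ValidationError(f"raw_signal must be >= 0, got {self.raw_signal}")
        if self.replicate < 1:
            raise ValidationError(f"replicate must be >= 1, got {self.replicate}")
        if self.role is Role.TEST:
            if not self.drug_id:
                raise ValidationError("test well must name a drug")
            if not self.conc > 0:
                raise ValidationError(
                    f"test well must have conc > 0, got {self.conc}"
                )


@dataclass(frozen=True)
class TreatmentRecord:
    """One treatment round of one patient: a regimen and its RECIST outcome."""

    patient_id: str
    pdo_id: str
    round_index: int
    drugs: tuple[str, ...]
    outcome: Outcome

    def __post_init__(self) -> None:
        object.__setattr__(self, "drugs", tuple(self.drugs))
        object.__setattr__(self, "outcome", Outcome(self.outcome))
        if not self.drugs:
            raise ValidationError("treatment must list at least one drug")
        if self.round_index < 1:
            raise ValidationError("round_index must be >= 1")


@dataclass(frozen=True)
class SurvivalRecord:
    """One subject of the survival cohort (time in months unless stated)."""

    subject_id: str
    time: float
    event: bool
    group: str

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValidationError(f"time must be >= 0, got {self.time}")


@dataclass
class RunConfig:
    """All tunable thresholds of the pipeline, with the study defaults.

    tertile_fraction : 1/3 — tertile split of IC50 ranks per drug, also the
        censored-mass threshold that triggers the bound rule.
    de_fdr_max / de_fc_min : 0.01 / 2 — DE filter (BH q and linear fold
        change) for signature candidates.
    rho_min : 0.3 — minimum |Spearman rho| between expression and the
        six-drug IC50 summary.
    bootstrap_reps / ci_level : 1000 / 0.95 — percentile bootstrap of the
        concordance metrics.
    fixed_partner_viability : 0.70 — the fixed combination partner is dosed
        at its IC30, i.e. leaves 70% viability.
    """

    seed: int = 0
    tertile_fraction: float = 1.0 / 3.0
    de_fdr_max: float = 0.01
    de_fc_min: float = 2.0
    rho_min: float = 0.3
    bootstrap_reps: int = 1000
    ci_level: float = 0.95
    fixed_partner_viability: float = 0.70
    noise_cv: float = 0.10
    qc_cv_limit: float = 0.20
    moderate_counts_as_good: bool = False
    normalization: str = "two_anchor"  # or "neg_only"

    def __post_init__(self) -> None:
        if not 0 < self.tertile_fraction < 0.5:
            raise ValidationError("tertile_fraction must be in (0, 0.5)")
        if not 0 < self.de_fdr_max <= 1:
            raise ValidationError("de_fdr_max must be in (0, 1]")
        if self.de_fc_min < 1:
            raise ValidationError("de_fc_min must be >= 1")
        if not 0 <= self.rho_min < 1:
            raise ValidationError("rho_min must be in [0, 1)")
        if self.bootstrap_reps < 1:
            raise ValidationError("bootstrap_reps must be >= 1")
        if not 0 < self.ci_level < 1:
            raise ValidationError("ci_level must be in (0, 1)")
        if not 0 < self.fixed_partner_viability <= 1:
            raise ValidationError("fixed_partner_viability must be in (0, 1]")
        if self.noise_cv < 0:
            raise ValidationError("noise_cv must be >= 0")
        if self.normalization not in ("two_anchor", "neg_only"):
            raise ValidationError(f"unknown normalization {self.normalization!r}")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        import hashlib

        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def dilution_series(top_conc: float, fold: float, n_points: int) -> np.ndarray:
    """Descending dilution series: element k is ``top_conc / fold**k``.

    With the default screen settings (20 µM top, threefold, 7 points) the
    last element is 20e-6 / 3**6 = 2.743e-8 M, i.e. 27.4 nM.
    """
    if not top_conc > 0:
        raise ValueError(f"top_conc must be > 0, got {top_conc}")
    if not fold > 1:
        raise ValueError(f"fold must be > 1, got {fold}")
    if n_points < 1:
        raise ValueError(f"n_points must be >= 1, got {n_points}")
    return top_conc / fold ** np.arange(n_points, dtype=float)


def format_conc(conc_molar: float) -> str:
    """Human-readable concentration, choosing µM or nM by magnitude."""
    if conc_molar >= 1e-6:
        return f"{conc_molar * 1e6:.3g} µM"
    return f"{conc_molar * 1e9:.3g} nM"


# The six microtubule-targeting drugs whose joint response defines the
# transcriptomic signature groups.
MICROTUBULE_DRUGS: tuple[str, ...] = (
    "docetaxel",
    "paclitaxel",
    "vinorelbine",
    "ixabepilone",
    "vincristine",
    "vinblastine",
)

_BREAST_APPROVED = (
    ("docetaxel", "microtubule"),
    ("paclitaxel", "microtubule"),
    ("vinorelbine", "microtubule"),
    ("ixabepilone", "microtubule"),
    ("eribulin", "microtubule"),
    ("epirubicin", "topoisomerase II"),
    ("doxorubicin", "topoisomerase II"),
    ("mitoxantrone", "topoisomerase II"),
    ("cyclophosphamide", "alkylating"),
    ("capecitabine", "antimetabolite"),
    ("fluorouracil", "antimetabolite"),
    ("methotrexate", "antimetabolite"),
    ("gemcitabine", "antimetabolite"),
    ("carboplatin", "platinum"),
    ("cisplatin", "platinum"),
    ("lapatinib", "HER2/EGFR"),
    ("neratinib", "HER2/EGFR"),
    ("palbociclib", "CDK4/6"),
    ("everolimus", "mTOR"),
)

_OTHER_CANCERS = (
    ("vincristine", "microtubule"),
    ("vinblastine", "microtubule"),
    ("bortezomib", "proteasome"),
    ("cantharidin", "protein/DNA/RNA synthesis"),
    ("topotecan", "topoisomerase I"),
    ("irinotecan", "topoisomerase I"),
    ("etoposide", "topoisomerase II"),
    ("cladribine", "antimetabolite"),
    ("cytarabine", "antimetabolite"),
    ("pemetrexed", "antimetabolite"),
    ("decitabine", "antimetabolite"),
    ("azacitidine", "antimetabolite"),
    ("cepharanthine", "NF-kB"),
    ("afatinib", "EGFR"),
    ("gefitinib", "EGFR"),
    ("erlotinib", "EGFR"),
    ("dacomitinib", "EGFR"),
    ("temsirolimus", "mTOR"),
    ("sunitinib", "multi-kinase"),
    ("sorafenib", "multi-kinase"),
    ("imatinib", "BCR-ABL"),
    ("dasatinib", "BCR-ABL/SRC"),
    ("crizotinib", "ALK"),
    ("olaparib", "PARP"),
    ("vorinostat", "HDAC"),
    ("romidepsin", "HDAC"),
    ("bendamustine", "alkylating"),
    ("ifosfamide", "alkylating"),
    ("oxaliplatin", "platinum"),
    ("bleomycin", "DNA damage"),
)


def default_panel(top_conc: float = 20e-6, fold: float = 3.0, n_points: int = 7
                  ) -> list[DrugPanelEntry]:
    """The default 49-drug screening panel: 19 drugs approved for breast
    cancer plus 30 repurposing candidates approved for other cancers, all
    on a 7-point threefold series from 20 µM."""
    panel = [
        DrugPanelEntry(d, t, top_conc, fold, n_points, approved_for_breast=True)
        for d, t in _BREAST_APPROVED
    ]
    panel += [
        DrugPanelEntry(d, t, top_conc, fold, n_points, approved_for_breast=False)
        for d, t in _OTHER_CANCERS
    ]
    return panel


# ---------------------------------------------------------------------------
# table readers / writers


_PLATE_COLUMNS = ["pdo_id", "drug_id", "conc_molar", "replicate", "signal", "role"]


def _read_df(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix in (".tsv", ".txt") else ","
    return pd.read_csv(path, sep=sep, dtype={"pdo_id": str, "drug_id": str,
                                             "patient_id": str, "subject_id": str})


def _require_columns(df: pd.DataFrame, cols: Sequence[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"{what} is missing column(s): {', '.join(missing)}")


def read_plate_table(path: str | Path,
                     panel: Sequence[DrugPanelEntry] | None = None
                     ) -> list[PlateWell]:
    """Read a long-format plate table; validate each well.

    Control wells may leave drug and concentration empty.  If a panel is
    given, test-well drugs and concentrations are checked against it.
    """
    df = _read_df(path)
    _require_columns(df, _PLATE_COLUMNS, "plate table")
    by_drug = {e.drug_id: e for e in panel} if panel is not None else None
    wells = []
    for idx, row in enumerate(df.itertuples(index=False)):
        drug = "" if pd.isna(row.drug_id) else str(row.drug_id)
        conc = 0.0 if pd.isna(row.conc_molar) else float(row.conc_molar)
        try:
            well = PlateWell(str(row.pdo_id), drug, conc, int(row.replicate),
                             float(row.signal), Role(row.role))
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"plate table row {idx}: {exc}") from exc
        if by_drug is not None and well.role is Role.TEST:
            entry = by_drug.get(well.drug_id)
            if entry is None:
                raise ValidationError(
                    f"plate table row {idx}: drug {well.drug_id!r} not in panel")
            lo, hi = entry.min_conc, entry.top_conc
            if not (lo * 0.999 <= well.conc <= hi * 1.001):
                raise ValidationError(
                    f"plate table row {idx}: conc {format_conc(well.conc)} outside"
                    f" tested range [{format_conc(lo)}, {format_conc(hi)}]")
        wells.append(well)
    return wells


def plate_frame(wells: Iterable[PlateWell]) -> pd.DataFrame:
    return pd.DataFrame(
        [(w.pdo_id, w.drug_id, w.conc, w.replicate, w.raw_signal, w.role.value)
         for w in wells],
        columns=_PLATE_COLUMNS,
    )


def write_plate_table(wells: Iterable[PlateWell], path: str | Path) -> None:
    write_table(plate_frame(wells), path)


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a TSV/CSV deterministically (fixed float format, LF endings)."""
    path = Path(path)
    sep = "\t" if path.suffix in (".tsv", ".txt") else ","
    df.to_csv(path, sep=sep, index=False, float_format="%.10g",
              lineterminator="\n")


def read_table(path: str | Path) -> pd.DataFrame:
    return _read_df(path)


def write_panel(panel: Sequence[DrugPanelEntry], path: str | Path) -> None:
    data = [dataclasses.asdict(e) for e in panel]
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def read_panel(path: str | Path) -> list[DrugPanelEntry]:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, list):
        raise FormatError("panel file must contain a list of drug entries")
    return [DrugPanelEntry(**entry) for entry in data]


_TREATMENT_COLUMNS = ["patient_id", "pdo_id", "round_index", "drugs", "outcome"]


def write_treatments(records: Iterable[TreatmentRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [(r.patient_id, r.pdo_id, r.round_index, "+".join(r.drugs),
          r.outcome.value) for r in records],
        columns=_TREATMENT_COLUMNS,
    )
    write_table(df, path)


def read_treatments(path: str | Path) -> list[TreatmentRecord]:
    df = _read_df(path)
    _require_columns(df, _TREATMENT_COLUMNS, "treatment table")
    return [
        TreatmentRecord(str(r.patient_id), str(r.pdo_id), int(r.round_index),
                        tuple(str(r.drugs).split("+")), Outcome(r.outcome))
        for r in df.itertuples(index=False)
    ]


_SURVIVAL_COLUMNS = ["subject_id", "time", "event", "group"]


def write_survival(records: Iterable[SurvivalRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [(r.subject_id, r.time, int(r.event), r.group) for r in records],
        columns=_SURVIVAL_COLUMNS,
    )
    write_table(df, path)


def read_survival(path: str | Path) -> list[SurvivalRecord]:
    df = _read_df(path)
    _require_columns(df, _SURVIVAL_COLUMNS, "survival table")
    return [
        SurvivalRecord(str(r.subject_id), float(r.time), bool(r.event),
                       str(r.group))
        for r in df.itertuples(index=False)
    ]
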