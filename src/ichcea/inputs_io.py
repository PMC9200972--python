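"""Model inputs: domain types, bundled fixtures, config I/O and validation.

The model's health states are the seven levels of the modified Rankin Scale
(mRS): 0 = no symptoms through 5 = severe disability, with 6 = death as the
absorbing state.  Everything the cohort model consumes is collected in a
single :class:`ModelInputs` bundle:

* an entry cohort (counts over mRS 0-6 observed a few months after the
  index intracerebral hemorrhage, plus a mean entry age),
* raw transition counts for the two within-first-year phases (3->6 months
  and 6->9 / 9->12 months), converted to row-stochastic matrices,
* per-state utility weights with 95% CIs (QALY weight per year lived),
* per-state direct healthcare costs in 2019 euros for three phases
  (one-off 0-3 months, quarterly 3-12 months, quarterly beyond 1 year),
* an annual life table for background mortality,
* excess-mortality hazard ratios per mRS state for the long-term phase,
* economic settings (willingness-to-pay, differential discount rates,
  cycle length, stopping rules).

Three entry cohorts ship as fixtures (``cohort1``: an ICH-score validation
cohort, mean age 70; ``cohort2``: the TICH-2 trial control arm, mean age 69;
``cohort3``: the MISTIE-III trial control arm, mean age 62), together with
the transition counts, utilities, cost tables and a synthetic life table.
Reproducing published Dutch results requires substituting the national
life table via ``lifetable.csv`` (columns ``age,qx``).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

N_STATES = 7
MRS_DEAD = 6

FIXTURE_COHORTS = ("cohort1", "cohort2", "cohort3")

_COHORT_META = {
    "cohort1": ("ICH-score 12-month validation cohort", 70.0, 3.0),
    "cohort2": ("TICH-2 trial control arm", 69.0, 3.0),
    "cohort3": ("MISTIE-III trial control arm", 62.0, 1.0),
}

# Long-term hazard ratios on background mortality. mRS 0-1 carry no excess
# risk; mRS 2 and 5 anchor at 1.11 and 2.38, mRS 3-4 are linearly
# interpolated between the anchors (overridable in config).
_HR_LO, _HR_HI = 1.11, 2.38
DEFAULT_EXCESS_HR = (
    1.0,
    1.0,
    _HR_LO,
    _HR_LO + (_HR_HI - _HR_LO) / 3.0,
    _HR_LO + 2.0 * (_HR_HI - _HR_LO) / 3.0,
    _HR_HI,
)


class InputError(ValueError):
    """A referenced input file is missing or unreadable."""


class ValidationError(ValueError):
    """A model input violates one of its documented invariants."""


def _as_float_array(x, n=None) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    if n is not None and a.shape != (n,):
        raise ValidationError(f"expected {n} values, got shape {a.shape}")
    return a


@dataclass(frozen=True)
class CohortSpec:
    """An entry cohort: mRS counts at model entry plus demographics."""

    id: str
    label: str
    mean_entry_age: float
    entry_time_months: float
    counts: tuple[int, ...]
    source: str = ""

    def __post_init__(self):
        counts = tuple(int(c) for c in self.counts)
        object.__setattr__(self, "counts", counts)
        if len(counts) != N_STATES:
            raise ValidationError("cohort counts must have exactly 7 entries")

    @property
    def n(self) -> int:
        return sum(self.counts)

    def distribution(self) -> np.ndarray:
        return counts_to_distribution(self.counts)


@dataclass(frozen=True)
class TransitionCounts:
    """Raw 7x7 transition counts for the two within-first-year phases.

    ``phase_a`` covers the 3->6 month interval; ``phase_b`` is applied at
    both the 6->9 and 9->12 month steps.
    """

    phase_a: np.ndarray
    phase_b: np.ndarray

    def __post_init__(self):
        for name in ("phase_a", "phase_b"):
            m = np.asarray(getattr(self, name), dtype=int)
            if m.shape != (N_STATES, N_STATES):
                raise ValidationError(f"{name} must be 7x7")
            object.__setattr__(self, name, m)


@dataclass(frozen=True)
class UtilitySet:
    """Per-state annual utility weights with 95% CI bounds."""

    mean: np.ndarray
    lower95: np.ndarray
    upper95: np.ndarray

    def __post_init__(self):
        for name in ("mean", "lower95", "upper95"):
            object.__setattr__(self, name, _as_float_array(getattr(self, name), N_STATES))


@dataclass(frozen=True)
class CostPhaseSet:
    """Per-state costs (EUR) for the three post-ICH phases.

    Arrays have shape (7, 3): column 0 is the one-off 0-3 month block,
    column 1 the quarterly 3-12 month cost, column 2 the quarterly cost
    beyond one year.
    """

    mean: np.ndarray
    lower95: np.ndarray
    upper95: np.ndarray

    def __post_init__(self):
        for name in ("mean", "lower95", "upper95"):
            m = np.asarray(getattr(self, name), dtype=float)
            if m.shape != (N_STATES, 3):
                raise ValidationError(f"cost {name} must have shape (7, 3)")
            object.__setattr__(self, name, m)

    def phase(self, k: int) -> np.ndarray:
        """Mean cost vector for phase ``k`` in {1, 2, 3}."""
        return self.mean[:, k - 1]


@dataclass(frozen=True)
class LifeTable:
    """Annual probabilities of death q(a) by integer age."""

    age: np.ndarray
    qx: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "age", np.asarray(self.age, dtype=int))
        object.__setattr__(self, "qx", np.asarray(self.qx, dtype=float))
        if self.age.shape != self.qx.shape or self.age.ndim != 1:
            raise ValidationError("life table age/qx must be 1-D and congruent")

    @property
    def terminal_age(self) -> int:
        return int(self.age[-1])

    def q(self, age: float) -> float:
        """Annual death probability at ``floor(age)``, clamped to the table."""
        a = int(np.floor(age))
        if a <= self.age[0]:
            return float(self.qx[0])
        if a >= self.terminal_age:
            return 1.0
        return float(self.qx[a - int(self.age[0])])

    def annual_hazard(self, age: float) -> float:
        q = self.q(age)
        if q >= 1.0:
            return np.inf
        return -np.log1p(-q)


@dataclass(frozen=True)
class ExcessMortality:
    """Hazard multipliers on background mortality for alive states mRS 0-5."""

    hr: np.ndarray = field(default_factory=lambda: np.array(DEFAULT_EXCESS_HR))

    def __post_init__(self):
        object.__setattr__(self, "hr", _as_float_array(self.hr, N_STATES - 1))


@dataclass(frozen=True)
class EconSettings:
    """Economic evaluation settings.

    Defaults follow Dutch guidance: willingness-to-pay of EUR 80,000 per
    QALY (high disease burden), effects discounted at 1.5%/year and costs
    at 4%/year. The model cycle is a quarter year.
    """

    wtp: float = 80_000.0
    discount_rate_effects: float = 0.015
    discount_rate_costs: float = 0.04
    cycle_length: float = 0.25
    max_age: float = 105.0
    survival_epsilon: float = 1e-9
    half_cycle_correction: bool = False


@dataclass(frozen=True)
class ModelInputs:
    """Everything the cohort model needs, validated as a bundle."""

    cohort: CohortSpec
    transitions: TransitionCounts
    utilities: UtilitySet
    costs: CostPhaseSet
    life_table: LifeTable
    excess: ExcessMortality
    econ: EconSettings = field(default_factory=EconSettings)


# ---------------------------------------------------------------------------
# Derivations


def counts_to_distribution(counts: Sequence[int]) -> np.ndarray:
    """Convert mRS counts to an occupancy distribution (proportions)."""
    c = np.asarray(counts, dtype=float)
    if c.shape != (N_STATES,):
        raise ValidationError("counts must have exactly 7 entries")
    if np.any(c < 0):
        raise ValidationError("counts must be non-negative")
    total = c.sum()
    if total <= 0:
        raise ValidationError("counts must sum to a positive total")
    return c / total


def _rows_to_stochastic(counts: np.ndarray) -> np.ndarray:
    out = np.zeros((N_STATES, N_STATES))
    for i in range(N_STATES):
        total = counts[i].sum()
        if total > 0:
            out[i] = counts[i] / total
        else:
            # no observations: state retains itself rather than silently
            # renormalising
            out[i, i] = 1.0
    return out


def counts_to_row_stochastic(tc: TransitionCounts) -> tuple[np.ndarray, np.ndarray]:
    """Derive the phase-A and phase-B row-stochastic transition matrices."""
    return _rows_to_stochastic(tc.phase_a), _rows_to_stochastic(tc.phase_b)


# ---------------------------------------------------------------------------
# Validation


def validate_inputs(inputs: ModelInputs) -> list[str]:
    """Check every documented invariant; return the list of violations.

    An empty list means the bundle is valid. This is report-based so a
    caller can surface all problems at once; :func:`load_inputs` raises on
    a non-empty report.
    """
    v: list[str] = []
    c = inputs.cohort
    if sum(c.counts) <= 0:
        v.append("CohortSpec: counts must sum to a positive total")
    if any(x < 0 for x in c.counts):
        v.append("CohortSpec: counts must be non-negative")
    if not (18.0 <= c.mean_entry_age <= 100.0):
        v.append("CohortSpec: mean_entry_age must lie in [18, 100]")

    for name, m in (("phase_a", inputs.transitions.phase_a), ("phase_b", inputs.transitions.phase_b)):
        if np.any(m < 0):
            v.append(f"TransitionCounts.{name}: counts must be non-negative")
        dead = m[MRS_DEAD]
        if dead.sum() > 0 and (dead.sum() != dead[MRS_DEAD]):
            v.append(f"TransitionCounts.{name}: death row must be absorbing")

    u = inputs.utilities
    if np.any(u.lower95 > u.mean) or np.any(u.mean > u.upper95):
        v.append("UtilitySet: requires lower95 <= mean <= upper95 per state")
    if u.mean[MRS_DEAD] != 0.0:
        v.append("UtilitySet: utility of death (mRS 6) must be exactly 0")
    if np.any(np.abs(u.mean) > 1.0):
        v.append("UtilitySet: mean utilities must lie in [-1, 1]")

    k = inputs.costs
    if np.any(k.mean < 0) or np.any(k.lower95 < 0):
        v.append("CostPhaseSet: costs must be non-negative")
    if np.any(k.lower95 > k.mean) or np.any(k.mean > k.upper95):
        v.append("CostPhaseSet: requires lower95 <= mean <= upper95 per state/phase")
    if k.mean[MRS_DEAD, 2] != 0.0:
        v.append("CostPhaseSet: long-term cost for mRS 6 must be 0")

    lt = inputs.life_table
    if np.any(np.diff(lt.age) != 1):
        v.append("LifeTable: ages must be contiguous integer years")
    if np.any((lt.qx < 0) | (lt.qx > 1)):
        v.append("LifeTable: q values must lie in [0, 1]")
    if lt.qx[-1] != 1.0:
        v.append("LifeTable: terminal age must have q = 1")

    hr = inputs.excess.hr
    if hr[0] != 1.0 or hr[1] != 1.0:
        v.append("ExcessMortality: mRS 0 and 1 must carry multiplier 1.0")
    if np.any(np.diff(hr[2:]) < 0) or hr[2] < hr[1]:
        v.append("ExcessMortality: multipliers must be non-decreasing in mRS")
    if np.any(hr < 0):
        v.append("ExcessMortality: multipliers must be non-negative")

    e = inputs.econ
    if not (0.0 <= e.discount_rate_effects < 1.0 and 0.0 <= e.discount_rate_costs < 1.0):
        v.append("EconSettings: discount rates must lie in [0, 1)")
    if e.wtp < 0:
        v.append("EconSettings: willingness-to-pay must be non-negative")
    if e.cycle_length != 0.25:
        v.append("EconSettings: cycle_length is fixed at 0.25 years")

    # cross-checks
    if not (lt.age[0] <= c.mean_entry_age <= lt.terminal_age):
        v.append("cross-check: cohort mean_entry_age outside life-table age range")
    if e.max_age > lt.terminal_age + 1:
        v.append("cross-check: max_age extends beyond the life table")
    return v


# ---------------------------------------------------------------------------
# Fixtures


def _fixture_path(name: str):
    return resources.files("ichcea.data").joinpath(name)


def _read_fixture_csv(name: str) -> pd.DataFrame:
    with resources.as_file(_fixture_path(name)) as p:
        return pd.read_csv(p, float_precision="round_trip")


def _cohort_from_frame(df: pd.DataFrame, id: str, label: str, age: float, months: float, source: str) -> CohortSpec:
    df = df.sort_values("mrs")
    return CohortSpec(id=id, label=label, mean_entry_age=age,
                      entry_time_months=months, counts=tuple(df["count"]), source=source)


def fixture_cohort(name: str) -> CohortSpec:
    """One of the three bundled entry cohorts: cohort1 | cohort2 | cohort3."""
    if name not in _COHORT_META:
        raise InputError(f"unknown fixture cohort {name!r}; choose from {FIXTURE_COHORTS}")
    label, age, months = _COHORT_META[name]
    return _cohort_from_frame(_read_fixture_csv(f"{name}.csv"), name, label, age, months, "bundled fixture")


def _transitions_from_frames(a: pd.DataFrame, b: pd.DataFrame) -> TransitionCounts:
    cols = [f"to_mrs{j}" for j in range(N_STATES)]

    def mat(df):
        return df.sort_values("from_mrs")[cols].to_numpy(dtype=int)

    return TransitionCounts(phase_a=mat(a), phase_b=mat(b))


def fixture_transitions() -> TransitionCounts:
    return _transitions_from_frames(_read_fixture_csv("transitions_phase_a.csv"),
                                    _read_fixture_csv("transitions_phase_b.csv"))


def _utilities_from_frame(df: pd.DataFrame) -> UtilitySet:
    df = df.sort_values("mrs")
    return UtilitySet(mean=df["mean"].to_numpy(), lower95=df["lower95"].to_numpy(),
                      upper95=df["upper95"].to_numpy())


def fixture_utilities() -> UtilitySet:
    return _utilities_from_frame(_read_fixture_csv("utilities.csv"))


def _costs_from_frame(df: pd.DataFrame) -> CostPhaseSet:
    mean = np.zeros((N_STATES, 3))
    lo = np.zeros((N_STATES, 3))
    hi = np.zeros((N_STATES, 3))
    for _, row in df.iterrows():
        s, p = int(row["mrs"]), int(row["phase"])
        mean[s, p - 1] = row["mean"]
        lo[s, p - 1] = row["lower95"]
        hi[s, p - 1] = row["upper95"]
    return CostPhaseSet(mean=mean, lower95=lo, upper95=hi)


def fixture_costs() -> CostPhaseSet:
    return _costs_from_frame(_read_fixture_csv("costs.csv"))


def _life_table_from_frame(df: pd.DataFrame) -> LifeTable:
    df = df.sort_values("age")
    return LifeTable(age=df["age"].to_numpy(), qx=df["qx"].to_numpy())


def fixture_life_table() -> LifeTable:
    """The bundled synthetic (Gompertz-Makeham) life table."""
    return _life_table_from_frame(_read_fixture_csv("lifetable_synthetic.csv"))


def default_inputs(cohort: str = "cohort1", *, life_table: LifeTable | None = None,
                   econ: EconSettings | None = None) -> ModelInputs:
    """Fully populated inputs from the bundled fixtures.

    ``life_table`` defaults to the synthetic fixture; pass a national table
    to reproduce published absolute results.
    """
    inputs = ModelInputs(
        cohort=fixture_cohort(cohort),
        transitions=fixture_transitions(),
        utilities=fixture_utilities(),
        costs=fixture_costs(),
        life_table=life_table if life_table is not None else fixture_life_table(),
        excess=ExcessMortality(),
        econ=econ if econ is not None else EconSettings(),
    )
    report = validate_inputs(inputs)
    if report:
        raise ValidationError("; ".join(report))
    return inputs


# ---------------------------------------------------------------------------
# Config loading / saving


def _resolve(base: Path, ref: str) -> Path:
    p = Path(ref)
    return p if p.is_absolute() else base / p


def _read_csv(path: Path) -> pd.DataFrame:
    if not path.exists():
        raise InputError(f"input file not found: {path}")
    return pd.read_csv(path, float_precision="round_trip")


def _load_cohort(section, base: Path) -> CohortSpec:
    if isinstance(section, str):
        return fixture_cohort(section)
    if not isinstance(section, Mapping):
        raise InputError("cohort section must be a fixture name or a mapping")
    label = section.get("label", section.get("id", "custom"))
    age = float(section.get("mean_entry_age", 70.0))
    months = float(section.get("entry_time_months", 3.0))
    source = section.get("source", "config")
    if "file" in section:
        df = _read_csv(_resolve(base, section["file"])).sort_values("mrs")
        counts = tuple(df["count"])
    elif "counts" in section:
        counts = tuple(section["counts"])
    else:
        raise InputError("cohort mapping needs 'file' or 'counts'")
    return CohortSpec(id=section.get("id", "custom"), label=label, mean_entry_age=age,
                      entry_time_months=months, counts=counts, source=source)


def load_inputs(config_path: str | Path) -> ModelInputs:
    """Load and validate :class:`ModelInputs` from a YAML/JSON config.

    Every section is optional; omitted sections fall back to the bundled
    fixtures and documented defaults. Sections may inline values or point
    to CSV files (paths relative to the config file).
    """
    path = Path(config_path)
    if not path.exists():
        raise InputError(f"config file not found: {path}")
    cfg = yaml.safe_load(path.read_text()) or {}
    base = path.parent

    cohort = _load_cohort(cfg.get("cohort", "cohort1"), base)

    tsec = cfg.get("transitions")
    if tsec is None:
        transitions = fixture_transitions()
    else:
        transitions = _transitions_from_frames(
            _read_csv(_resolve(base, tsec["phase_a"])),
            _read_csv(_resolve(base, tsec["phase_b"])),
        )

    usec = cfg.get("utilities")
    if usec is None:
        utilities = fixture_utilities()
    elif isinstance(usec, str):
        utilities = _utilities_from_frame(_read_csv(_resolve(base, usec)))
    else:
        utilities = _utilities_from_frame(pd.DataFrame(usec))

    csec = cfg.get("costs")
    if csec is None:
        costs = fixture_costs()
    elif isinstance(csec, str):
        costs = _costs_from_frame(_read_csv(_resolve(base, csec)))
    else:
        costs = _costs_from_frame(pd.DataFrame(csec))

    lsec = cfg.get("life_table")
    if lsec is None:
        life_table = fixture_life_table()
    else:
        life_table = _life_table_from_frame(_read_csv(_resolve(base, lsec)))

    esec = cfg.get("excess_mortality")
    excess = ExcessMortality() if esec is None else ExcessMortality(hr=np.asarray(esec, dtype=float))

    known = {f.name for f in dataclasses.fields(EconSettings)}
    esettings = dict(cfg.get("econ") or {})
    unknown = set(esettings) - known
    if unknown:
        raise InputError(f"unknown econ settings: {sorted(unknown)}")
    econ = EconSettings(**esettings)

    inputs = ModelInputs(cohort=cohort, transitions=transitions, utilities=utilities,
                         costs=costs, life_table=life_table, excess=excess, econ=econ)
    report = validate_inputs(inputs)
    if report:
        raise ValidationError("; ".join(report))
    return inputs


def save_inputs(inputs: ModelInputs, directory: str | Path) -> Path:
    """Write the bundle as config.yaml + CSVs; round-trips bit-identically."""
    out = Path(directory)
    out.mkdir(parents=True, exist_ok=True)
    fmt = lambda x: repr(float(x))

    c = inputs.cohort
    pd.DataFrame({"mrs": range(N_STATES), "count": c.counts}).to_csv(out / "cohort.csv", index=False)
    for name, m in (("transitions_phase_a", inputs.transitions.phase_a),
                    ("transitions_phase_b", inputs.transitions.phase_b)):
        df = pd.DataFrame(m, columns=[f"to_mrs{j}" for j in range(N_STATES)])
        df.insert(0, "from_mrs", range(N_STATES))
        df.to_csv(out / f"{name}.csv", index=False)
    u = inputs.utilities
    pd.DataFrame({"mrs": range(N_STATES), "mean": [fmt(x) for x in u.mean],
                  "lower95": [fmt(x) for x in u.lower95],
                  "upper95": [fmt(x) for x in u.upper95]}).to_csv(out / "utilities.csv", index=False)
    rows = []
    for s in range(N_STATES):
        for p in (1, 2, 3):
            rows.append({"mrs": s, "phase": p, "mean": fmt(inputs.costs.mean[s, p - 1]),
                         "lower95": fmt(inputs.costs.lower95[s, p - 1]),
                         "upper95": fmt(inputs.costs.upper95[s, p - 1])})
    pd.DataFrame(rows).to_csv(out / "costs.csv", index=False)
    pd.DataFrame({"age": inputs.life_table.age,
                  "qx": [fmt(x) for x in inputs.life_table.qx]}).to_csv(out / "lifetable.csv", index=False)

    e = inputs.econ
    cfg = {
        "cohort": {"id": c.id, "label": c.label, "mean_entry_age": c.mean_entry_age,
                   "entry_time_months": c.entry_time_months, "file": "cohort.csv",
                   "source": c.source},
        "transitions": {"phase_a": "transitions_phase_a.csv", "phase_b": "transitions_phase_b.csv"},
        "utilities": "utilities.csv",
        "costs": "costs.csv",
        "life_table": "lifetable.csv",
        "excess_mortality": [float(x) for x in inputs.excess.hr],
        "econ": {f.name: getattr(e, f.name) for f in dataclasses.fields(EconSettings)},
    }
    cfg_path = out / "config.yaml"
    cfg_path.write_text(yaml.safe_dump(cfg, sort_keys=False))
    return cfg_path
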