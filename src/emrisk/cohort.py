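"""Case-control cohort construction from longitudinal EMR event tables.

For each PTSD patient the pipeline:

1. groups diagnosis codes to their 3-character ICD category,
2. keeps only abnormal-flagged lab results of sufficiently frequent tests,
3. picks the index date: the *latest* encounter strictly after the first
   PTSD diagnosis and strictly before the first ASUD diagnosis (if any),
   mimicking the patient's latest pre-outcome status,
4. labels the patient a *case* if an ASUD record falls within the 90 days
   after the index date, a *control* otherwise, with exclusions for
   same-day PTSD+ASUD, ASUD preceding PTSD, and ASUD within the year
   before the index date,
5. packs the trailing-year (365-day) events into a chronologically ordered
   visit sequence with inter-visit gaps, appends SDoH tokens at the index
   date, and
6. builds a frequency-ranked token vocabulary and a seeded 8:1:1
   train/validation/test split.

Calendar conventions ("3 months" = 90 days, half-open (index, index+90];
"1 year" = 365 days, closed [index-365, index]) are fixed-day windows for
reproducibility. Token multiplicity within a visit is preserved because
downstream feature contributions sum over repeated occurrences.

The labeling logic lives in integer-day kernels shared by the per-patient
DataFrame operations and the vectorized whole-table build, so the two paths
cannot drift apart.
"""

from __future__ import annotations

import json
import logging
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import sdoh as sdoh_mod

logger = logging.getLogger(__name__)

ABNORMAL_FLAGS = frozenset({"ABNORMAL", "HIGH", "LOW"})
PAD_TOKEN = "<pad>"
DEFAULT_PTSD_CODES = frozenset({"309.81", "F43.10", "F43.11", "F43.12"})
DEFAULT_WINDOW_DAYS = 90
DEFAULT_LOOKBACK_DAYS = 365
DEFAULT_MIN_LAB_FREQUENCY = 100
DEFAULT_VOCAB_SIZE = 30_000

_PUNCT = re.compile(r"[^0-9A-Za-z]")


def normalize_code(code: str) -> str:
    """Strip punctuation and uppercase, e.g. 'F43.10' -> 'F4310'."""
    return _PUNCT.sub("", str(code)).upper()


def group_code(code: str) -> str:
    """Group a diagnosis code to its 3-character ICD category.

    Punctuation is stripped and the code uppercased before truncation
    ('F43.10' -> 'F43'). Codes shorter than 3 characters after cleaning are
    kept as-is with a warning. Applied identically to ICD-9 and ICD-10.
    """
    cleaned = normalize_code(code)
    if len(cleaned) < 3:
        warnings.warn(f"diagnosis code {code!r} shorter than 3 characters; kept as-is")
        return cleaned
    return cleaned[:3]


@dataclass(frozen=True)
class CodeSets:
    """Outcome-defining ICD-9/10 code sets (full codes, pre-grouping)."""

    ptsd_codes: frozenset[str]
    asud_codes: frozenset[str]

    def __post_init__(self):
        ptsd = frozenset(normalize_code(c) for c in self.ptsd_codes)
        asud = frozenset(normalize_code(c) for c in self.asud_codes)
        if not ptsd or not asud:
            raise ValueError("code sets must be non-empty")
        if ptsd & asud:
            raise ValueError("PTSD and ASUD code sets must be disjoint")
        object.__setattr__(self, "ptsd_codes", ptsd)
        object.__setattr__(self, "asud_codes", asud)

    def is_ptsd(self, code: str) -> bool:
        return normalize_code(code) in self.ptsd_codes

    def is_asud(self, code: str) -> bool:
        return normalize_code(code) in self.asud_codes

    @classmethod
    def from_yaml(cls, path) -> "CodeSets":
        import yaml

        with open(path) as fh:
            payload = yaml.safe_load(fh)
        return cls(
            ptsd_codes=frozenset(str(c) for c in payload["ptsd_codes"]),
            asud_codes=frozenset(str(c) for c in payload["asud_codes"]),
        )


@dataclass
class CohortSample:
    """One labeled patient instance: index date, lookback visit sequence."""

    patient_id: str
    index_date: pd.Timestamp
    label: str                                  # 'case' or 'control'
    visits: list[tuple[pd.Timestamp, tuple[str, ...]]]
    gap_days: list[int]
    sdoh_tokens: tuple[str, ...] = ()

    def all_tokens(self):
        for _, tokens in self.visits:
            yield from tokens

    @property
    def y(self) -> int:
        return 1 if self.label == "case" else 0


@dataclass
class Vocabulary:
    """Injective token -> integer-id map; id 0 is reserved for padding/unknown."""

    token_to_id: dict[str, int]
    max_size: int = DEFAULT_VOCAB_SIZE

    @property
    def size(self) -> int:
        return len(self.token_to_id) + 1  # + reserved pad id

    @property
    def pad_id(self) -> int:
        return 0

    def encode(self, token: str) -> int:
        return self.token_to_id.get(token, 0)

    def decode(self, idx: int) -> str:
        if not hasattr(self, "_id_to_token"):
            self._id_to_token = {i: t for t, i in self.token_to_id.items()}
        return self._id_to_token.get(idx, PAD_TOKEN)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"max_size": self.max_size, "token_to_id": self.token_to_id},
                fh, indent=2, sort_keys=True,
            )

    @classmethod
    def from_json(cls, path) -> "Vocabulary":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(token_to_id=payload["token_to_id"], max_size=payload["max_size"])


# ---------------------------------------------------------------------------
# event-level preprocessing
# ---------------------------------------------------------------------------

def filter_labs(events: pd.DataFrame, min_frequency: int = DEFAULT_MIN_LAB_FREQUENCY) -> pd.DataFrame:
    """Keep abnormal-flagged lab events of sufficiently frequent tests.

    Retains lab events whose flag is ABNORMAL/HIGH/LOW and whose lab code
    occurs at least ``min_frequency`` times dataset-wide, the frequency
    being counted after the flag filter ("less than 100 times" is
    exclusive, so exactly 100 occurrences is retained). Non-lab channels
    pass through unchanged.
    """
    is_lab = events["channel"] == "lab"
    abnormal = is_lab & events["flag"].isin(ABNORMAL_FLAGS)
    counts = events.loc[abnormal, "code"].value_counts()
    frequent = set(counts[counts >= min_frequency].index)
    keep = ~is_lab | (abnormal & events["code"].isin(frequent))
    return events.loc[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# integer-day labeling kernels
# ---------------------------------------------------------------------------

def _index_day(days: np.ndarray, ptsd_days: np.ndarray, asud_days: np.ndarray):
    """Latest encounter day strictly after first PTSD, strictly before first ASUD."""
    if ptsd_days.size == 0:
        raise ValueError("patient has no PTSD diagnosis")
    first_ptsd = ptsd_days.min()
    eligible = days[days > first_ptsd]
    if asud_days.size:
        eligible = eligible[eligible < asud_days.min()]
    return int(eligible.max()) if eligible.size else None


def _label_day(index_day: int, ptsd_days: np.ndarray, asud_days: np.ndarray,
               window_days: int, lookback_days: int) -> tuple[str, str]:
    first_ptsd = ptsd_days.min()
    if asud_days.size == 0:
        return "control", "no_asud_record"
    first_asud = asud_days.min()
    if first_asud == first_ptsd:
        return "excluded", "asud_same_day_as_ptsd"
    if first_asud < first_ptsd:
        return "excluded", "asud_before_ptsd"
    if ((asud_days >= index_day - lookback_days) & (asud_days <= index_day)).any():
        return "excluded", "asud_in_lookback_year"
    if ((asud_days > index_day) & (asud_days <= index_day + window_days)).any():
        return "case", "asud_within_window"
    return "control", "asud_after_window"


def _patient_arrays(patient_events: pd.DataFrame, code_sets: CodeSets):
    dates = pd.to_datetime(patient_events["date"])
    days = (dates.astype("int64") // 86_400_000_000_000).to_numpy()
    dx = (patient_events["channel"] == "diagnosis").to_numpy()
    codes = patient_events["code"].astype(str)
    is_ptsd = dx & codes.map(code_sets.is_ptsd).to_numpy()
    is_asud = dx & codes.map(code_sets.is_asud).to_numpy()
    return days, days[is_ptsd], days[is_asud]


def select_index_date(patient_events: pd.DataFrame, code_sets: CodeSets) -> pd.Timestamp | None:
    """Latest encounter strictly after first PTSD and strictly before first ASUD.

    Any event date counts as an encounter. Returns None when no eligible
    encounter exists; raises when the patient has no PTSD diagnosis.
    """
    days, ptsd_days, asud_days = _patient_arrays(patient_events, code_sets)
    d = _index_day(days, ptsd_days, asud_days)
    return None if d is None else pd.Timestamp(d, unit="D")


@dataclass(frozen=True)
class LabelDecision:
    label: str            # 'case', 'control' or 'excluded'
    reason: str


def assign_label(
    patient_events: pd.DataFrame,
    index_date: pd.Timestamp,
    code_sets: CodeSets,
    window_days: int = DEFAULT_WINDOW_DAYS,
) -> LabelDecision:
    """Case/control/excluded decision for one patient at a given index date.

    Excluded when (a) the first ASUD record falls on the same day as the
    first PTSD diagnosis, (b) any ASUD precedes the first PTSD diagnosis,
    or (c) any ASUD falls within the year before the index date. A case has
    an ASUD record in the half-open window (index, index + window_days];
    anything else is a control, even if ASUD occurs after the window.
    """
    _, ptsd_days, asud_days = _patient_arrays(patient_events, code_sets)
    idx = int(pd.Timestamp(index_date).value // 86_400_000_000_000)
    label, reason = _label_day(idx, ptsd_days, asud_days, window_days, DEFAULT_LOOKBACK_DAYS)
    return LabelDecision(label, reason)


def build_sequence(
    patient_events: pd.DataFrame,
    index_date: pd.Timestamp,
    lookback_days: int = DEFAULT_LOOKBACK_DAYS,
    vocabulary: Vocabulary | None = None,
    sdoh_tokens: tuple[str, ...] = (),
) -> tuple[list, list]:
    """Pack a patient's lookback events into an ordered visit sequence.

    Groups tokens by encounter date within [index - lookback, index],
    preserving within-visit multiplicity, and appends SDoH tokens at the
    index-date visit. Returns (visits, gap_days); the first gap is 0.
    ``vocabulary`` is accepted for interface completeness; encoding to ids
    happens at model-input time so one sequence can serve several vocabularies.
    """
    events = patient_events.copy()
    events["date"] = pd.to_datetime(events["date"])
    lo = index_date - pd.Timedelta(days=lookback_days)
    window = events[(events["date"] >= lo) & (events["date"] <= index_date)]
    by_date: dict[pd.Timestamp, list[str]] = {}
    for date, code in zip(window["date"], window["code"]):
        by_date.setdefault(date, []).append(code)
    if sdoh_tokens:
        by_date.setdefault(pd.Timestamp(index_date), []).extend(sdoh_tokens)
    dates = sorted(by_date)
    visits = [(d, tuple(sorted(by_date[d]))) for d in dates]
    gaps = [0] + [int((b - a).days) for a, b in zip(dates, dates[1:])]
    return visits, gaps


def build_vocabulary(samples: list[CohortSample], max_size: int = DEFAULT_VOCAB_SIZE) -> Vocabulary:
    """Frequency-ranked vocabulary over all sample tokens.

    Keeps the ``max_size - 1`` most frequent tokens (id 0 is reserved for
    padding/unknown); ties are broken lexicographically so ids are stable.
    """
    counts: dict[str, int] = {}
    for s in samples:
        for tok in s.all_tokens():
            counts[tok] = counts.get(tok, 0) + 1
    ranked = sorted(counts, key=lambda t: (-counts[t], t))[: max_size - 1]
    return Vocabulary(token_to_id={t: i + 1 for i, t in enumerate(ranked)}, max_size=max_size)


def split_dataset(samples: list[CohortSample], seed: int, ratios=(0.8, 0.1, 0.1)):
    """Seeded random 8:1:1 patient-level partition (disjoint, exhaustive)."""
    if len(samples) < 10:
        raise ValueError("need at least 10 samples to split 8:1:1")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(samples))
    n_train = int(np.floor(ratios[0] * len(samples)))
    n_val = int(np.floor(ratios[1] * len(samples)))
    train = [samples[i] for i in order[:n_train]]
    val = [samples[i] for i in order[n_train:n_train + n_val]]
    test = [samples[i] for i in order[n_train + n_val:]]
    return train, val, test


# ---------------------------------------------------------------------------
# end-to-end cohort build
# ---------------------------------------------------------------------------

@dataclass
class CohortResult:
    samples: list[CohortSample]
    vocabulary: Vocabulary
    audit: pd.DataFrame                      # patient_id, decision, reason
    token_channels: dict[str, str] = field(default_factory=dict)

    @property
    def cases(self) -> list[CohortSample]:
        return [s for s in self.samples if s.label == "case"]

    @property
    def controls(self) -> list[CohortSample]:
        return [s for s in self.samples if s.label == "control"]


def build_cohort(
    events: pd.DataFrame,
    code_sets: CodeSets,
    demographics: pd.DataFrame | None = None,
    sdoh_table: pd.DataFrame | None = None,
    *,
    include_sdoh: bool = True,
    min_lab_frequency: int = DEFAULT_MIN_LAB_FREQUENCY,
    window_days: int = DEFAULT_WINDOW_DAYS,
    lookback_days: int = DEFAULT_LOOKBACK_DAYS,
    vocab_size: int = DEFAULT_VOCAB_SIZE,
) -> CohortResult:
    """Run the full data-preparation pipeline over an event table."""
    events = events.copy()
    events["date"] = pd.to_datetime(events["date"])

    # lab filtering is dataset-wide; diagnosis codes are grouped for the
    # sequences while PTSD/ASUD identification uses the raw (full) codes
    filtered = filter_labs(events, min_frequency=min_lab_frequency)
    raw_codes = filtered["code"].astype(str)
    dx_mask = (filtered["channel"] == "diagnosis").to_numpy()
    unique_codes = pd.unique(raw_codes)
    group_map = {c: group_code(c) for c in unique_codes}
    tokens = raw_codes.map(group_map).to_numpy(dtype=object)
    tokens[~dx_mask] = raw_codes.to_numpy(dtype=object)[~dx_mask]

    token_channels: dict[str, str] = {}
    channels = filtered["channel"].to_numpy(dtype=object)
    for tok, ch in zip(tokens, channels):
        token_channels.setdefault(tok, ch)

    is_ptsd_code = {c: code_sets.is_ptsd(c) for c in unique_codes}
    is_asud_code = {c: code_sets.is_asud(c) for c in unique_codes}
    is_ptsd = dx_mask & raw_codes.map(is_ptsd_code).to_numpy()
    is_asud = dx_mask & raw_codes.map(is_asud_code).to_numpy()

    pids = filtered["patient_id"].to_numpy(dtype=object)
    days = (filtered["date"].astype("int64") // 86_400_000_000_000).to_numpy()
    order = np.lexsort((days, pids))
    pids, days, tokens = pids[order], days[order], tokens[order]
    is_ptsd, is_asud = is_ptsd[order], is_asud[order]
    unique_pids, starts = np.unique(pids, return_index=True)
    bounds = np.append(starts, len(pids))

    # SDoH token lookup tables (precomputed once)
    zip_tokens: dict[str, tuple[str, ...]] = {}
    demo_rows: dict[str, dict] = {}
    if include_sdoh and sdoh_table is not None and demographics is not None:
        tokenization = sdoh_mod.fit_tokenization(sdoh_table)
        for _, zrow in sdoh_table.iterrows():
            zip_tokens[str(zrow["zip"])] = tuple(
                tokenization.bin_token(name, float(zrow[name]))
                for name in tokenization.index_names
            )
        unknown = tuple(f"{name.upper()}:UNKNOWN" for name in tokenization.index_names)
        demo_rows = {str(r["patient_id"]): dict(r) for _, r in demographics.iterrows()}
    else:
        tokenization = None

    samples: list[CohortSample] = []
    audit_rows: list[tuple[str, str, str]] = []

    for i, pid in enumerate(unique_pids):
        sl = slice(bounds[i], bounds[i + 1])
        p_days = days[sl]
        p_ptsd = p_days[is_ptsd[sl]]
        p_asud = p_days[is_asud[sl]]
        if p_ptsd.size == 0:
            audit_rows.append((pid, "skipped", "no_ptsd_diagnosis"))
            continue
        # patient-level exclusions are index-independent and come first
        if p_asud.size:
            if p_asud.min() == p_ptsd.min():
                audit_rows.append((pid, "excluded", "asud_same_day_as_ptsd"))
                continue
            if p_asud.min() < p_ptsd.min():
                audit_rows.append((pid, "excluded", "asud_before_ptsd"))
                continue
        index_day = _index_day(p_days, p_ptsd, p_asud)
        if index_day is None:
            audit_rows.append((pid, "skipped", "no_eligible_encounter"))
            continue
        label, reason = _label_day(index_day, p_ptsd, p_asud, window_days, lookback_days)
        if label == "excluded":
            audit_rows.append((pid, "excluded", reason))
            continue

        sdoh_tokens: tuple[str, ...] = ()
        if tokenization is not None and pid in demo_rows:
            row = demo_rows[pid]
            index_date = pd.Timestamp(index_day, unit="D")
            toks = set(sdoh_mod.encode_individual(row, index_date))
            toks.update(zip_tokens.get(str(row.get("zip")), unknown))
            sdoh_tokens = tuple(sorted(toks))
            for t in sdoh_tokens:
                token_channels.setdefault(t, "sdoh")

        # lookback sequence: visits grouped by day, chronological
        in_window = (p_days >= index_day - lookback_days) & (p_days <= index_day)
        w_days = p_days[in_window]
        w_tokens = tokens[sl][in_window]
        visit_days, visit_starts = np.unique(w_days, return_index=True)
        visit_bounds = np.append(visit_starts, len(w_days))
        by_day = {
            int(d): list(w_tokens[visit_bounds[k]:visit_bounds[k + 1]])
            for k, d in enumerate(visit_days)
        }
        if sdoh_tokens:
            by_day.setdefault(index_day, []).extend(sdoh_tokens)
        if not by_day:
            audit_rows.append((pid, "dropped", "empty_sequence"))
            logger.info("patient %s dropped: empty sequence after filtering", pid)
            continue
        day_list = sorted(by_day)
        visits = [(pd.Timestamp(d, unit="D"), tuple(sorted(by_day[d]))) for d in day_list]
        gaps = [0] + [int(b - a) for a, b in zip(day_list, day_list[1:])]
        samples.append(
            CohortSample(
                patient_id=pid, index_date=pd.Timestamp(index_day, unit="D"),
                label=label, visits=visits, gap_days=gaps, sdoh_tokens=sdoh_tokens,
            )
        )
        audit_rows.append((pid, label, reason))

    vocabulary = build_vocabulary(samples, max_size=vocab_size) if samples else Vocabulary({}, vocab_size)
    audit = pd.DataFrame(audit_rows, columns=["patient_id", "decision", "reason"])
    return CohortResult(samples=samples, vocabulary=vocabulary, audit=audit,
                        token_channels=token_channels)


# ---------------------------------------------------------------------------
# serialization (CLI artifacts)
# ---------------------------------------------------------------------------

def save_samples(samples: list[CohortSample], path) -> None:
    """Serialize samples as JSON lines (one patient per line)."""
    with open(path, "w") as fh:
        for s in samples:
            fh.write(json.dumps({
                "patient_id": s.patient_id,
                "index_date": s.index_date.strftime("%Y-%m-%d"),
                "label": s.label,
                "visits": [[d.strftime("%Y-%m-%d"), list(tokens)] for d, tokens in s.visits],
                "gap_days": s.gap_days,
                "sdoh_tokens": list(s.sdoh_tokens),
            }, sort_keys=True) + "\n")


def load_samples(path) -> list[CohortSample]:
    samples = []
    with open(path) as fh:
        for line in fh:
            d = json.loads(line)
            samples.append(CohortSample(
                patient_id=d["patient_id"],
                index_date=pd.Timestamp(d["index_date"]),
                label=d["label"],
                visits=[(pd.Timestamp(dt), tuple(toks)) for dt, toks in d["visits"]],
                gap_days=list(d["gap_days"]),
                sdoh_tokens=tuple(d["sdoh_tokens"]),
            ))
    return samples
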