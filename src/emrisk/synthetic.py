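"""Seeded synthetic longitudinal EMR populations with planted effects.

Real EMR streams of the kind this package targets (multi-year visit
histories of PTSD patients with coded diagnoses, medication fills and
flagged laboratory results) sit behind data-use agreements, so the package
ships a generator that emulates their structure with a *known* outcome
mechanism. Every patient receives a PTSD diagnosis; visits arrive as a
homogeneous Poisson process; each visit carries random multisets of
diagnosis / medication / lab tokens; and the onset of the alcohol-and-
substance-use-disorder (ASUD) outcome is drawn per encounter window from a
Bernoulli whose logit is

    baseline_logit + sum of planted log-odds weights of the tokens present
    in the trailing 365 days (plus the patient's static SDoH tokens)

which makes downstream estimates (odds ratios, relative contributions)
analytically interpretable. All randomness flows from one root seed split
into independent sub-streams, so identical config + seed reproduces the
population byte for byte.

The generator is a study-conditions definition, not a dial: its defaults
(visit rate, observation span, baseline logit) were chosen once to yield a
roughly balanced case/control cohort comparable in prevalence to published
PTSD->ASUD cohorts, and the token vocabularies are desk-scale so planted
signals are recoverable at a few thousand patients.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from . import sdoh as sdoh_mod

BASE_DATE = pd.Timestamp("2010-01-01")
LAB_FLAGS = ("ABNORMAL", "HIGH", "LOW", "NORMAL")

# Letters used for synthetic ICD-like 3-character diagnosis groups. 'F' is
# reserved so random codes never collide with the PTSD (F43.*) or ASUD
# (F10.*) code families.
_DX_LETTERS = "ABCDEGHJKLMN"

DEFAULT_PTSD_CODE = "F43.10"
DEFAULT_ASUD_CODE = "F10.20"

# zip-level neighborhood index distributions: name -> (mean, sd)
DEFAULT_SDOH_INDICES: dict[str, tuple[float, float]] = {
    "nses": (0.0, 1.0),
    "racial_segregation": (0.0, 0.4),
    "aridity": (0.5, 0.15),
    "urban": (0.0, 1.0),
    "transport_barrier": (0.10, 0.05),
}


class ConfigError(ValueError):
    """Invalid simulation configuration (e.g. planted token not in vocabulary)."""


def planted_signal_effects() -> dict[str, float]:
    """Standard planted-signal study condition used by tests and examples.

    A mix of risk (log-odds > 0) and protective (< 0) effects across the
    diagnosis, medication, lab and SDoH channels, strong enough that a
    well-specified classifier reaches clearly-better-than-chance
    discrimination at a few thousand patients. Pair with
    ``baseline_logit=PLANTED_SIGNAL_BASELINE`` to keep the resulting cohort
    roughly case/control balanced.
    """
    ln = np.log
    return {
        "A01": ln(4.0), "A12": ln(3.0), "A23": ln(3.0), "A34": ln(2.5),
        "LAB003": ln(2.5), "RX0005": ln(1 / 4), "RX0011": ln(1 / 3),
        "A45": ln(0.4), "TRANSPORT_BARRIER:Q4": ln(2.0), "NSES:Q1": ln(1.8),
    }


PLANTED_SIGNAL_BASELINE = -4.5


def diagnosis_vocabulary(n: int) -> list[str]:
    codes = [f"{letter}{num:02d}" for letter in _DX_LETTERS for num in range(100)]
    if n > len(codes):
        raise ConfigError(f"diagnosis vocabulary capped at {len(codes)}")
    return codes[:n]


def medication_vocabulary(n: int) -> list[str]:
    return [f"RX{i:04d}" for i in range(n)]


def lab_vocabulary(n: int) -> list[str]:
    return [f"LAB{i:03d}" for i in range(n)]


@dataclass
class SimConfig:
    """Study conditions for one synthetic population."""

    n_patients: int = 1000
    obs_years: float = 4.0
    visit_rate: float = 8.0            # expected visits / patient / year
    vocab_sizes: dict[str, int] = field(
        default_factory=lambda: {"diagnosis": 60, "medication": 40, "lab": 25}
    )
    tokens_per_visit: dict[str, float] = field(
        default_factory=lambda: {"diagnosis": 1.3, "medication": 1.0, "lab": 1.2}
    )
    lab_flag_probs: dict[str, float] = field(
        default_factory=lambda: {"ABNORMAL": 0.30, "HIGH": 0.20, "LOW": 0.15, "NORMAL": 0.35}
    )
    planted_effects: dict[str, float] = field(default_factory=dict)
    baseline_logit: float = -3.5
    outcome_window_days: int = 90
    ptsd_code: str = DEFAULT_PTSD_CODE
    asud_code: str = DEFAULT_ASUD_CODE
    # probability that a post-diagnosis visit re-codes the PTSD diagnosis,
    # mimicking chronic-condition recoding; keeps the PTSD token frequent in
    # lookback windows so it can serve as the reference feature
    ptsd_recode_prob: float = 0.25
    n_zips: int = 40
    sdoh_indices: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_SDOH_INDICES)
    )
    seed: int = 0

    @property
    def obs_days(self) -> int:
        return int(round(self.obs_years * 365))

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ConfigError("n_patients must be >= 1")
        if self.visit_rate <= 0:
            raise ConfigError("visit_rate must be > 0")
        if self.outcome_window_days <= 0:
            raise ConfigError("outcome_window_days must be > 0")
        if abs(sum(self.lab_flag_probs.values()) - 1.0) > 1e-9:
            raise ConfigError("lab_flag_probs must sum to 1")


@dataclass
class GroundTruth:
    """What the generator knows that an analyst would have to estimate."""

    planted_effects: dict[str, float]
    outcome_date: dict[str, str | None]            # patient_id -> ISO date or None
    linear_predictor: dict[str, float]             # logit at the final evaluated window
    # one row per evaluated (patient, encounter) window: date, converted,
    # plus a 0/1 presence column per planted token
    window_log: pd.DataFrame


@dataclass
class Population:
    events: pd.DataFrame
    demographics: pd.DataFrame
    sdoh_zip: pd.DataFrame
    truth: GroundTruth
    config: SimConfig


def _valid_planted_tokens(config: SimConfig, tokenization) -> set[str]:
    valid = set(diagnosis_vocabulary(config.vocab_sizes["diagnosis"]))
    valid |= set(medication_vocabulary(config.vocab_sizes["medication"]))
    valid |= set(lab_vocabulary(config.vocab_sizes["lab"]))
    valid |= tokenization.all_tokens()
    valid |= {f"SEX:{s}" for s in ("F", "M")}
    valid |= {f"RACE:{r}" for r in ("WHITE", "BLACK", "ASIAN", "OTHER")}
    valid |= {f"AGE:{lo}-{lo + 9}" for lo in range(0, 120, 10)}
    return valid


def generate_population(config: SimConfig) -> Population:
    """Generate one seeded population (events, demographics, zip SDoH, truth)."""
    config.validate()
    root = np.random.SeedSequence(config.seed)
    rng_structure, rng_tokens, rng_sdoh, rng_outcome = (
        np.random.default_rng(s) for s in root.spawn(4)
    )

    n = config.n_patients
    obs_days = config.obs_days
    patient_ids = np.array([f"P{i:06d}" for i in range(n)])

    # --- zip-level SDoH table -------------------------------------------
    zips = np.array([f"15{i:03d}" for i in range(config.n_zips)])
    sdoh_cols = {"zip": zips}
    for name, (mean, sd) in config.sdoh_indices.items():
        sdoh_cols[name] = rng_sdoh.normal(mean, sd, config.n_zips)
    sdoh_zip = pd.DataFrame(sdoh_cols)
    tokenization = sdoh_mod.fit_tokenization(sdoh_zip) if config.n_zips >= 4 else None

    if tokenization is not None:
        valid = _valid_planted_tokens(config, tokenization)
        unknown = set(config.planted_effects) - valid
        if unknown:
            raise ConfigError(f"planted tokens not in any vocabulary: {sorted(unknown)}")

    # --- demographics ----------------------------------------------------
    ages = rng_sdoh.integers(18, 81, n)
    demographics = pd.DataFrame(
        {
            "patient_id": patient_ids,
            "birth_year": BASE_DATE.year - ages,
            "sex": rng_sdoh.choice(["F", "M"], n, p=[0.6, 0.4]),
            "race": rng_sdoh.choice(
                ["White", "Black", "Asian", "Other"], n, p=[0.65, 0.20, 0.05, 0.10]
            ),
            "zip": rng_sdoh.choice(zips, n),
        }
    )

    # --- visit skeleton --------------------------------------------------
    ptsd_day = rng_structure.integers(0, max(1, obs_days // 2), n)
    n_visits = rng_structure.poisson(config.visit_rate * config.obs_years, n)
    visit_pid_idx = np.repeat(np.arange(n), n_visits)
    visit_day = rng_structure.integers(0, obs_days, n_visits.sum())
    order = np.lexsort((visit_day, visit_pid_idx))
    visit_pid_idx, visit_day = visit_pid_idx[order], visit_day[order]

    event_pid: list[np.ndarray] = []
    event_day: list[np.ndarray] = []
    event_channel: list[np.ndarray] = []
    event_code: list[np.ndarray] = []
    event_flag: list[np.ndarray] = []

    def _emit(pids, days, channel, codes, flags=None):
        m = len(pids)
        event_pid.append(np.asarray(pids))
        event_day.append(np.asarray(days))
        event_channel.append(np.full(m, channel, dtype=object))
        event_code.append(np.asarray(codes, dtype=object))
        event_flag.append(
            np.asarray(flags, dtype=object) if flags is not None
            else np.full(m, "", dtype=object)
        )

    # initial PTSD diagnosis: one per patient
    _emit(patient_ids, ptsd_day, "diagnosis", np.full(n, config.ptsd_code, dtype=object))

    # chronic re-coding of the PTSD diagnosis at post-diagnosis visits
    post = visit_day > ptsd_day[visit_pid_idx]
    recode = post & (rng_tokens.random(visit_day.size) < config.ptsd_recode_prob)
    _emit(
        patient_ids[visit_pid_idx[recode]],
        visit_day[recode],
        "diagnosis",
        np.full(int(recode.sum()), config.ptsd_code, dtype=object),
    )

    # per-visit random multisets per channel
    vocabs = {
        "diagnosis": np.array(diagnosis_vocabulary(config.vocab_sizes["diagnosis"]), dtype=object),
        "medication": np.array(medication_vocabulary(config.vocab_sizes["medication"]), dtype=object),
        "lab": np.array(lab_vocabulary(config.vocab_sizes["lab"]), dtype=object),
    }
    flag_names = np.array(LAB_FLAGS, dtype=object)
    flag_probs = np.array([config.lab_flag_probs[f] for f in LAB_FLAGS])
    for channel in ("diagnosis", "medication", "lab"):
        counts = rng_tokens.poisson(config.tokens_per_visit[channel], visit_day.size)
        total = int(counts.sum())
        tok_idx = rng_tokens.integers(0, len(vocabs[channel]), total)
        pids = patient_ids[np.repeat(visit_pid_idx, counts)]
        days = np.repeat(visit_day, counts)
        flags = (
            rng_tokens.choice(flag_names, total, p=flag_probs) if channel == "lab" else None
        )
        _emit(pids, days, channel, vocabs[channel][tok_idx], flags)

    # --- static SDoH token sets (for the outcome mechanism) --------------
    planted = dict(config.planted_effects)
    planted_tokens = list(planted)
    sdoh_presence = np.zeros((n, len(planted_tokens)), dtype=bool)
    if tokenization is not None and planted_tokens:
        zip_to_tokens = {
            str(row["zip"]): {
                tokenization.bin_token(name, float(row[name]))
                for name in tokenization.index_names
            }
            for _, row in sdoh_zip.iterrows()
        }
        demo_records = demographics.to_dict("records")
        for i in range(n):
            row = demo_records[i]
            tokens = sdoh_mod.encode_individual(row, BASE_DATE + pd.Timedelta(days=int(ptsd_day[i])))
            tokens |= zip_to_tokens[str(row["zip"])]
            for j, tok in enumerate(planted_tokens):
                sdoh_presence[i, j] = tok in tokens

    # --- occurrence days of planted channel tokens, per patient ----------
    all_pid = np.concatenate(event_pid)
    all_day = np.concatenate(event_day).astype(np.int64)
    all_code = np.concatenate(event_code)
    occ: dict[str, dict[str, np.ndarray]] = {}
    channel_token_set = set().union(*(set(v) for v in vocabs.values()))
    for tok in planted_tokens:
        if tok not in channel_token_set:
            continue  # SDoH token: handled via static presence
        sel = all_code == tok
        pid_sel, day_sel = all_pid[sel], all_day[sel]
        o = np.lexsort((day_sel, pid_sel))
        pid_sel, day_sel = pid_sel[o], day_sel[o]
        bounds = np.searchsorted(pid_sel, patient_ids)
        bounds = np.append(bounds, len(pid_sel))
        occ[tok] = {
            pid: day_sel[bounds[i]:bounds[i + 1]] for i, pid in enumerate(patient_ids)
        }

    # --- outcome: per-window Bernoulli over post-diagnosis encounters ----
    weights = np.array([planted[t] for t in planted_tokens])
    visit_bounds = np.searchsorted(visit_pid_idx, np.arange(n + 1))
    outcome_date: dict[str, str | None] = {}
    linear_predictor: dict[str, float] = {}
    log_rows: list[tuple] = []
    asud_pids, asud_days = [], []

    for i, pid in enumerate(patient_ids):
        days_i = visit_day[visit_bounds[i]:visit_bounds[i + 1]]
        wins = np.unique(days_i[days_i > ptsd_day[i]])
        if wins.size == 0:
            outcome_date[pid] = None
            linear_predictor[pid] = float(config.baseline_logit)
            continue
        presence = np.zeros((wins.size, len(planted_tokens)))
        for j, tok in enumerate(planted_tokens):
            if tok in occ:
                d = occ[tok][pid]
                presence[:, j] = (
                    np.searchsorted(d, wins, side="right")
                    - np.searchsorted(d, wins - 365, side="left")
                ) > 0
            else:
                presence[:, j] = sdoh_presence[i, j]
        logits = config.baseline_logit + presence @ weights if planted_tokens else np.full(
            wins.size, config.baseline_logit
        )
        u = rng_outcome.random(wins.size)
        hit = u < expit(logits)
        k = int(np.argmax(hit)) if hit.any() else wins.size
        for w in range(min(k + 1, wins.size)):
            log_rows.append((pid, int(wins[w]), bool(hit[w]), *presence[w].astype(int)))
        if hit.any():
            onset = int(wins[k]) + int(rng_outcome.integers(1, config.outcome_window_days + 1))
            outcome_date[pid] = (BASE_DATE + pd.Timedelta(days=onset)).strftime("%Y-%m-%d")
            linear_predictor[pid] = float(logits[k])
            asud_pids.append(pid)
            asud_days.append(onset)
        else:
            outcome_date[pid] = None
            linear_predictor[pid] = float(logits[-1])

    if asud_pids:
        _emit(asud_pids, asud_days, "diagnosis",
              np.full(len(asud_pids), config.asud_code, dtype=object))

    # --- assemble --------------------------------------------------------
    events = pd.DataFrame(
        {
            "patient_id": np.concatenate(event_pid),
            "date": BASE_DATE + pd.to_timedelta(np.concatenate(event_day).astype(np.int64), unit="D"),
            "channel": np.concatenate(event_channel),
            "code": np.concatenate(event_code),
            "flag": np.concatenate(event_flag),
        }
    )
    events = events.sort_values(
        ["patient_id", "date", "channel", "code", "flag"], kind="mergesort"
    ).reset_index(drop=True)

    window_log = pd.DataFrame(
        log_rows, columns=["patient_id", "day", "converted", *planted_tokens]
    )
    truth = GroundTruth(
        planted_effects=planted,
        outcome_date=outcome_date,
        linear_predictor=linear_predictor,
        window_log=window_log,
    )
    return Population(events, demographics, sdoh_zip, truth, config)


# ---------------------------------------------------------------------------
# fixture I/O
# ---------------------------------------------------------------------------

def write_fixture(population: Population, directory) -> dict[str, Path]:
    """Write a population as CSV + JSON files that round-trip losslessly."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "events": directory / "events.csv",
        "demographics": directory / "demographics.csv",
        "sdoh_zip": directory / "sdoh_zip.csv",
        "truth": directory / "truth.json",
    }
    ev = population.events.copy()
    ev["date"] = ev["date"].dt.strftime("%Y-%m-%d")
    ev.to_csv(paths["events"], index=False)
    population.demographics.to_csv(paths["demographics"], index=False)
    population.sdoh_zip.to_csv(paths["sdoh_zip"], index=False, float_format="%.12g")
    with open(paths["truth"], "w") as fh:
        json.dump(
            {
                "planted_effects": population.truth.planted_effects,
                "outcome_date": population.truth.outcome_date,
            },
            fh,
            indent=2,
            sort_keys=True,
        )
    return paths


def read_events(path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        dtype={"patient_id": str, "channel": str, "code": str, "flag": str},
        keep_default_na=False,
    )
    df["date"] = pd.to_datetime(df["date"])
    return df


def read_demographics(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"patient_id": str, "zip": str, "sex": str, "race": str})


def read_sdoh(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"zip": str})


def read_truth(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
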