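"""State I–V segmentation of the arm-release process.

The release of the aminomethyl lipoate arm from the cavity of protein H
proceeds through five conformational states, each defined by the dominant
charged hydrogen bond between an arm nitrogen and a cavity residue:

=====  ==========  =====================================
State  arm atom    cavity partner
=====  ==========  =====================================
I      N17         Glu-12 or Glu-14 (protected state)
II     N17         Ser-67 (β7 sheet)
III    N17         Asp-68
IV     N17         Tyr-70 (cavity edge)
V      N6          Leu-35 (arm has left the cavity)
=====  ==========  =====================================

A frame with no arm–cavity bond is "released"; bonds matching no hallmark
give "none".  When several hallmarks co-occur the later state wins (the
release narrative is a forward progression).  Labels are smoothed by a
sliding majority vote, then a furthest-state-reached convention makes the
reported sequence non-decreasing so transient back-flickers cannot reset the
dwell clocks.  Step n is the time between entering state n and state n+1;
the release time is the entry into State V (first bond-free frame behind a
flag), matching the convention that State V marks the arm completely leaving
the cavity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError, StateDefinitionError
from .hbonds import ContactTable
from .topology import Topology

__all__ = [
    "StateDefinition", "StateLabels", "StepReport",
    "default_state_definitions", "label_frames", "smooth_labels",
    "step_report", "STATE_NAMES",
]

# label codes: ordering doubles as priority and as the furthest-state order
NONE, I, II, III, IV, V, RELEASED = range(7)
STATE_NAMES = ["none", "I", "II", "III", "IV", "V", "released"]
_CODE = {name: code for code, name in enumerate(STATE_NAMES)}


@dataclass(frozen=True)
class StateDefinition:
    """One hallmark: an arm atom bonded to any of some cavity residues."""

    state: str                                   # "I" ... "V"
    arm_atom: str
    cavity_residues: tuple[tuple[str, int], ...]

    @property
    def code(self) -> int:
        return _CODE[self.state]


def default_state_definitions() -> list[StateDefinition]:
    return [
        StateDefinition("I", "N17", (("GLU", 12), ("GLU", 14))),
        StateDefinition("II", "N17", (("SER", 67),)),
        StateDefinition("III", "N17", (("ASP", 68),)),
        StateDefinition("IV", "N17", (("TYR", 70),)),
        StateDefinition("V", "N6", (("LEU", 35),)),
    ]


@dataclass
class StateLabels:
    """Per-frame state assignment, as integer codes with name accessors."""

    times: np.ndarray
    codes: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.float64)
        self.codes = np.asarray(self.codes, dtype=np.int64)
        if self.times.shape != self.codes.shape:
            raise ValueError("times and codes must have equal length")

    @property
    def names(self) -> list[str]:
        return [STATE_NAMES[c] for c in self.codes]

    def __len__(self) -> int:
        return len(self.codes)

    def to_frame(self, smoothed: "StateLabels | None" = None) -> pd.DataFrame:
        df = pd.DataFrame({"frame": np.arange(len(self)),
                           "time_ns": self.times,
                           "raw_label": self.names})
        if smoothed is not None:
            df["smoothed_label"] = smoothed.names
        return df


def label_frames(table: ContactTable,
                 definitions: Sequence[StateDefinition] | None = None,
                 topology: Topology | None = None) -> StateLabels:
    """Assign each frame the highest-priority state whose hallmark is bonded.

    ``topology``, when given, is used to validate that every definition's
    atoms and residues actually exist (a misspelled hallmark otherwise just
    never fires).
    """
    defs = list(definitions) if definitions is not None \
        else default_state_definitions()
    if topology is not None:
        names = set(map(str, topology.names))
        residues = {(str(rn), int(ri)) for rn, ri
                    in zip(topology.res_names, topology.res_ids)}
        for d in defs:
            if d.arm_atom not in names:
                raise StateDefinitionError(
                    f"state {d.state}: arm atom {d.arm_atom!r} not in topology")
            for pair in d.cavity_residues:
                if (str(pair[0]), int(pair[1])) not in residues:
                    raise StateDefinitionError(
                        f"state {d.state}: residue {pair[0]}-{pair[1]} "
                        "not in topology")

    codes = np.full(table.n_frames, RELEASED, dtype=np.int64)
    df = table.records
    if len(df):
        # frames with any arm-cavity bond start as "none", hallmarks upgrade
        bonded_frames = df["frame"].to_numpy()
        codes[np.unique(bonded_frames)] = NONE
        key = (df["arm_atom"].astype(str) + "|"
               + df["cavity_res_name"].astype(str) + "|"
               + df["cavity_res_id"].astype(str))
        for d in sorted(defs, key=lambda s: s.code):  # later states overwrite
            wanted = {f"{d.arm_atom}|{rn}|{ri}" for rn, ri in d.cavity_residues}
            hit = np.unique(bonded_frames[key.isin(wanted).to_numpy()])
            codes[hit] = np.maximum(codes[hit], d.code)
    return StateLabels(times=table.times, codes=codes)


def smooth_labels(labels: StateLabels, window: int = 11) -> StateLabels:
    """Sliding majority vote; ties break toward the later (higher) state.

    The window must be odd so the vote is centered; ``window=1`` is the
    identity.  Edges use the truncated window.
    """
    if window < 1 or window % 2 == 0:
        raise ParameterError(f"smoothing window must be odd and >= 1, "
                             f"got {window}")
    if window == 1:
        return StateLabels(times=labels.times.copy(), codes=labels.codes.copy())
    half = window // 2
    n = len(labels)
    out = np.empty(n, dtype=np.int64)
    codes = labels.codes
    n_states = RELEASED + 1
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        counts = np.bincount(codes[lo:hi], minlength=n_states)
        best = counts.max()
        out[i] = np.flatnonzero(counts == best)[-1]  # tie -> higher state
    return StateLabels(times=labels.times.copy(), codes=out)


_RELEASE_UNDEFINED = None  # explicit sentinel: the arm never left State I


@dataclass
class StepReport:
    """Step durations (ns), release time, and traversal flags."""

    step_durations_ns: dict[str, float | None]
    release_time_ns: float | None
    skipped_states: list[str]
    furthest_state: str
    entry_times_ns: dict[str, float | None]
    started_in_state_i: bool = True
    warnings: list[str] = field(default_factory=list)

    def to_json(self, path=None) -> str:
        payload = json.dumps({
            "step_durations_ns": self.step_durations_ns,
            "release_time_ns": self.release_time_ns,
            "skipped_states": self.skipped_states,
            "furthest_state": self.furthest_state,
            "entry_times_ns": self.entry_times_ns,
            "started_in_state_i": self.started_in_state_i,
            "warnings": self.warnings,
        }, sort_keys=True, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload


def step_report(labels: StateLabels,
                release_on_bond_free: bool = False) -> StepReport:
    """Step durations and release time from (smoothed) labels.

    The furthest-state-reached convention is applied first: a frame labeled
    below the running maximum keeps the maximum, making the sequence
    non-decreasing.  Entry into state k is the first frame at or above k;
    Step n = entry(n+1) − entry(n).  A state passed over without a single
    frame of its own gets zero duration and a skipped flag.  The release time
    is the entry into State V (or, with ``release_on_bond_free``, the first
    fully bond-free frame); a trajectory that never leaves State I reports an
    explicit ``None`` sentinel, not an error.
    """
    furthest = np.maximum.accumulate(labels.codes)
    times = labels.times
    warnings: list[str] = []
    started_in_i = bool(len(furthest) and furthest[0] == I)
    if not started_in_i:
        warnings.append("trajectory does not begin in State I")

    def entry(code: int) -> float | None:
        hit = np.flatnonzero(furthest >= code)
        return float(times[hit[0]]) if len(hit) else None

    entries = {STATE_NAMES[c]: entry(c) for c in (I, II, III, IV, V, RELEASED)}

    durations: dict[str, float | None] = {}
    for n, (lo, hi) in enumerate(((I, II), (II, III), (III, IV), (IV, V)),
                                 start=1):
        e_lo, e_hi = entry(lo), entry(hi)
        if e_lo is None:
            durations[f"step{n}"] = 0.0        # never reached: trivially zero
        elif e_hi is None:
            durations[f"step{n}"] = None       # entered, never progressed
        else:
            durations[f"step{n}"] = e_hi - e_lo

    # a direct IV -> released transition is step 4 completing, not a skip,
    # so State V is never flagged here
    skipped = [STATE_NAMES[c] for c in (II, III, IV)
               if entry(c) is not None and not np.any(labels.codes == c)
               and np.any(furthest > c)]

    if release_on_bond_free:
        release = entry(RELEASED)
    else:
        release = entry(V)
    furthest_state = STATE_NAMES[int(furthest[-1])] if len(furthest) else "none"
    return StepReport(step_durations_ns=durations, release_time_ns=release,
                      skipped_states=skipped, furthest_state=furthest_state,
                      entry_times_ns=entries,
                      started_in_state_i=started_in_i, warnings=warnings)
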