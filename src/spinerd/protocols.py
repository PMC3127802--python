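"""Stimulation protocols: calcium/dopamine injection schedules emulating
LTP induction.

The four-train LTP protocol is four 1 s trains of 100 Hz stimulation with an
80 s inter-train interval.  Each pulse is a 0.7 ms calcium influx of 62.5
molecules/ms delivered independently at the PSD (NMDA-receptor influx) and
at a focal dendritic submembrane region (voltage-dependent calcium
channels).  Each train is accompanied by a 1 s dopamine transient (0.8
molecules/ms into the whole morphology, ~1 uM).  After each train an
irreversible calcium buffer (CaB) is injected to return calcium to its
resting level, standing in for the voltage-dependent extrusion dynamics the
chemical model does not represent.

Schedules are pure data: building one involves no randomness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .engine import InjectionEvent
from .mesh import Mesh

# printed stimulation parameters
CA_PULSE_RATE = 62.5  # molecules/ms, per influx site
CA_PULSE_WIDTH = 0.7e-3  # s
PULSE_INTERVAL = 0.01  # s (100 Hz)
PULSES_PER_TRAIN = 100
N_TRAINS = 4
TRAIN_INTERVAL = 80.0  # s, inter-train onset spacing
DA_RATE = 0.8  # molecules/ms
DA_DURATION = 1.0  # s


@dataclass
class StimulusSchedule:
    events: list[InjectionEvent]
    label: str = ""

    def __post_init__(self):
        self.events = sorted(self.events, key=lambda e: (e.onset, e.species, e.voxel_set))

    @property
    def end(self) -> float:
        return max((e.end for e in self.events), default=0.0)

    def ca_pulse_count(self) -> int:
        return sum(1 for e in self.events if e.species == "Ca" and e.voxel_set == "psd")

    def total_expected(self, species: str) -> float:
        return sum(e.expected_molecules for e in self.events if e.species == species)


def _require_sets(mesh: Mesh, names: list[str]):
    sets = mesh.metadata.get("sets", {})
    missing = [n for n in names if n not in sets or not sets[n]]
    if missing:
        raise ValueError(f"mesh lacks required voxel set(s): {missing}")


def _train_events(
    onset: float,
    psd_set: str,
    dend_set: str,
    n_pulses: int = PULSES_PER_TRAIN,
    pulse_interval: float = PULSE_INTERVAL,
) -> list[InjectionEvent]:
    ev = []
    for p in range(n_pulses):
        t = onset + p * pulse_interval
        ev.append(InjectionEvent("Ca", psd_set, CA_PULSE_RATE, t, CA_PULSE_WIDTH))
        ev.append(InjectionEvent("Ca", dend_set, CA_PULSE_RATE, t, CA_PULSE_WIDTH))
    return ev


def build_four_train_ltp(
    mesh: Mesh,
    n_trains: int = N_TRAINS,
    train_interval: float = TRAIN_INTERVAL,
    first_onset: float = 1.0,
    cab_amount: float | None = None,
    cab_duration: float = 1.0,
    psd_set: str = "psd",
    dend_set: str = "dendrite_ca_influx",
) -> StimulusSchedule:
    """Four 100 Hz trains with dopamine transients and post-train CaB.

    ``train_interval`` may be compressed for desk-scale runs (the default is
    the printed 80 s).  ``cab_amount`` defaults to the calcium injected per
    train, which returns spine calcium to near its resting level.
    """
    _require_sets(mesh, [psd_set, dend_set])
    if psd_set == "psd" and "stimulated_psd" in mesh.metadata.get("sets", {}):
        psd_set = "stimulated_psd"  # multi-spine: only the stimulated spines
    events: list[InjectionEvent] = []
    train_len = PULSES_PER_TRAIN * PULSE_INTERVAL
    if cab_amount is None:
        # both influx sites, all pulses of one train
        cab_amount = 2 * PULSES_PER_TRAIN * CA_PULSE_RATE * CA_PULSE_WIDTH * 1e3
    for k in range(n_trains):
        onset = first_onset + k * train_interval
        events += _train_events(onset, psd_set, dend_set)
        events.append(InjectionEvent("Da", "all", DA_RATE, onset, DA_DURATION))
        cab = build_cab_injection(
            mesh, amount=cab_amount, duration=cab_duration,
            onset=onset + train_len,
            influx_end=onset + train_len - PULSE_INTERVAL + CA_PULSE_WIDTH,
        )
        events += cab.events
    return StimulusSchedule(events, label=f"four_train_ltp_x{n_trains}_iti{train_interval:g}")


def build_single_ca_train(
    mesh: Mesh,
    onset: float = 0.1,
    psd_set: str = "psd",
    dend_set: str = "dendrite_ca_influx",
    cab_amount: float | None = None,
    cab_duration: float = 1.0,
) -> StimulusSchedule:
    """One 100-pulse train of calcium influx (10 ms interval, PSD + focal
    dendrite), no dopamine; CaB clean-up after the train."""
    _require_sets(mesh, [psd_set, dend_set])
    if psd_set == "psd" and "stimulated_psd" in mesh.metadata.get("sets", {}):
        psd_set = "stimulated_psd"
    events = _train_events(onset, psd_set, dend_set)
    train_len = PULSES_PER_TRAIN * PULSE_INTERVAL
    if cab_amount is None:
        cab_amount = 2 * PULSES_PER_TRAIN * CA_PULSE_RATE * CA_PULSE_WIDTH * 1e3
    events += build_cab_injection(
        mesh, amount=cab_amount, duration=cab_duration,
        onset=onset + train_len,
        influx_end=onset + train_len - PULSE_INTERVAL + CA_PULSE_WIDTH,
    ).events
    return StimulusSchedule(events, label="single_ca_train")


def build_cab_injection(
    mesh: Mesh,
    amount: float,
    duration: float,
    onset: float,
    influx_end: float | None = None,
) -> StimulusSchedule:
    """Inject ``amount`` molecules of the irreversible calcium buffer over
    ``duration`` s, uniformly over the morphology, starting after calcium
    influx has ceased."""
    if influx_end is not None and onset < influx_end:
        raise ValueError(
            f"CaB onset {onset} precedes the end of calcium influx {influx_end}"
        )
    if amount < 0:
        raise ValueError("amount must be >= 0")
    rate_ms = (amount / duration) * 1e-3 if duration > 0 else 0.0
    return StimulusSchedule(
        [InjectionEvent("CaB", "all", rate_ms, onset, duration)],
        label="cab_injection",
    )
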