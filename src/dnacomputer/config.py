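"""Structured-configuration interface (YAML) for all stages.

Config files use practitioner-friendly units (mA, µL, s, nM); everything is
converted to SI on load.  Any block or key may be omitted, in which case
the packaged defaults apply — see ``data/default_config.yaml`` for the full
annotated schema.
"""

from __future__ import annotations

from dataclasses import replace
from importlib import resources

import numpy as np
import yaml

from . import catalytic, fsm, gates, thresholder
from .electrochemistry import ElectrochemicalParams, SwitchModel
from .orchestrator import CycleConfig, InputEncoding

__all__ = ["load_config", "config_from_dict", "default_config_text"]

_NM = 1e-9


def default_config_text() -> str:
    """The packaged default configuration file, as text."""
    return (resources.files("dnacomputer") / "data" / "default_config.yaml").read_text()


def config_from_dict(raw: dict) -> CycleConfig:
    """Build a :class:`~dnacomputer.orchestrator.CycleConfig` from a config dict."""
    raw = raw or {}
    kwargs = {}

    ec = raw.get("electrochemistry", {})
    kwargs["electro"] = ElectrochemicalParams(
        current=float(ec.get("current_mA", 0.4)) * 1e-3,
        volume=float(ec.get("volume_uL", 100.0)) * 1e-6,
        pulse_duration=float(ec.get("pulse_duration_s", 20.0)),
        initial_pH=float(ec.get("initial_pH", 5.5)),
        meta={k: ec[k] for k in ("voltage_V", "resistance_kOhm") if k in ec},
    )
    sw = raw.get("switch", {})
    kwargs["switch"] = SwitchModel(
        pKa=float(sw.get("pKa", 7.5)),
        total_switch=float(sw.get("total_nM", 1.7)) * _NM,
    )

    cyc = raw.get("catalytic_cycle", {})
    if "rates" in cyc:
        kwargs["cycle_rates"] = catalytic.CycleRates.from_dict(cyc["rates"])
    kwargs["cycle_init"] = catalytic.CycleInitialState(
        substrate=float(cyc.get("substrate_nM", 11.0)) * _NM,
        fuel=float(cyc.get("fuel_nM", 11.0)) * _NM,
        total_switch=float(sw.get("total_nM", 1.7)) * _NM,
    )
    if "dt_s" in cyc or "n_steps" in cyc:
        kwargs["dt"] = float(cyc.get("dt_s", 0.05))
        kwargs["cycle_n_steps"] = int(cyc.get("n_steps", 150_000))

    th = raw.get("thresholder", {})
    kwargs["thresh_params"] = thresholder.ThresholderParams(
        k_release=np.asarray(th.get("k_m", 1e4), dtype=float),
        k_capture=np.asarray(th.get("k_tm", 1e7), dtype=float),
        carrier_tot=np.asarray(th.get("A_tot_nM", 20.0), dtype=float) * _NM,
        thr_tot=np.asarray(th.get("thr_tot_nM", [0.25, 0.5, 0.75, 1.0]),
                           dtype=float) * _NM,
    )
    if "duration_s" in th:
        kwargs["thresh_duration"] = float(th["duration_s"])

    ga = raw.get("gates", {})
    gate_kwargs = {}
    if "k_act" in ga:
        gate_kwargs["k_act"] = np.asarray(ga["k_act"], dtype=float)
    if "k_deact" in ga:
        gate_kwargs["k_deact"] = np.asarray(ga["k_deact"], dtype=float)
    if "gate_tot_nM" in ga:
        gate_kwargs["gate_tot"] = np.asarray(ga["gate_tot_nM"], dtype=float) * _NM
    kwargs["gate_params"] = gates.GateParams(**gate_kwargs)
    if "duration_s" in ga:
        kwargs["gate_duration"] = float(ga["duration_s"])

    fs = raw.get("fsm", {})
    kwargs["fsm_params"] = fsm.FsmDynamicsParams(
        rate=float(fs.get("rate_per_s", 1e-3)),
        block_interval=float(fs.get("block_interval_s", 240.0)),
        settle_time=float(fs.get("settle_time_s", 36_000.0)),
    )
    if "rules_file" in fs:
        kwargs["tensor"] = fsm.load_transition_rules(fs["rules_file"])

    orch = raw.get("orchestrator", {})
    kwargs["mode"] = orch.get("mode", "ideal_ob")
    enc = orch.get("encoding", {})
    encoding = InputEncoding()
    if "ob_nM" in enc:
        encoding = replace(encoding, ob_lookup={
            int(k): float(v) * _NM for k, v in enc["ob_nM"].items()
        })
    if "t_open_s" in enc:
        encoding = replace(encoding, topen_lookup={
            int(k): float(v) for k, v in enc["t_open_s"].items()
        })
    kwargs["encoding"] = encoding

    return CycleConfig(**kwargs)


def load_config(path=None) -> CycleConfig:
    """Load a YAML configuration file (packaged defaults when ``path`` is None)."""
    if path is None:
        raw = yaml.safe_load(default_config_text())
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    return config_from_dict(raw)
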