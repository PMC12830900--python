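"""End-to-end studies: synthetic benchmark or user data.

``run_synthetic_study`` generates N sessions with known ground truth, labels
choices with both the HMM and the Rescorla-Wagner labeler, runs the full
pupil / neural / mediation battery, and returns a report bundle (tidy tables
+ a JSON-able summary + a plain-text log), optionally written to disk.
``run_data_study`` runs the identical battery on user-supplied trial tables
and spike-count matrices after schema validation.

Trial indexing is 0-based internally; human-readable outputs keep the same
0-based trial ids as the input tables.  A lag of k means "k trials before
the event".
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior, neural, pupil as pupil_mod, stats as stats_mod, synth
from .behavior import EXPLORE

REQUIRED_TRIAL_COLUMNS = ("session", "trial", "choice", "reward", "pupil_z", "rt")


class SchemaError(ValueError):
    """Raised when an input table fails validation (exit code 2 territory)."""


@dataclass
class StudyConfig:
    """Everything needed to reproduce a run byte-for-byte."""

    n_sessions: int = 6
    trials_per_session: int = 400
    seed: int = 0
    bandit: synth.BanditConfig | None = None
    agent: synth.AgentConfig | None = None
    pupil: synth.PupilGenConfig | None = None
    neural: synth.NeuralGenConfig | None = None
    peri_window: int = 15
    match_k: int = 6
    min_matches: int = 10
    n_quantiles: int = 5
    wavelet_period: float = 5.0
    wavelet_cycles: int = 5
    n_boot: int = 1000
    hmm_restarts: int = 20
    rw_starts: int = 10
    out_dir: str | None = None

    def resolved(self) -> "StudyConfig":
        cfg = dataclasses.replace(self)
        cfg.bandit = cfg.bandit or synth.BanditConfig(n_trials=cfg.trials_per_session)
        cfg.agent = cfg.agent or synth.AgentConfig()
        cfg.pupil = cfg.pupil or synth.PupilGenConfig()
        cfg.neural = cfg.neural or synth.NeuralGenConfig()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self.resolved()), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key, sub in (
            ("bandit", synth.BanditConfig),
            ("agent", synth.AgentConfig),
            ("pupil", synth.PupilGenConfig),
            ("neural", synth.NeuralGenConfig),
        ):
            if raw.get(key) is not None:
                d = raw[key]
                if "bounds" in d and d["bounds"] is not None:
                    d["bounds"] = tuple(d["bounds"])
                raw[key] = sub(**d)
        return cls(**raw)


@dataclass
class StudyReport:
    tables: dict = field(default_factory=dict)     # name -> DataFrame
    summary: dict = field(default_factory=dict)
    log: list = field(default_factory=list)

    def write(self, out_dir: str | Path) -> dict:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        checksums = {}
        for name, df in sorted(self.tables.items()):
            p = out / f"{name}.csv"
            df.to_csv(p, index=False, float_format="%.10g")
            checksums[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
        sp = out / "summary.json"
        sp.write_text(json.dumps(self.summary, indent=2, sort_keys=True, default=_jsonify))
        checksums[sp.name] = hashlib.sha256(sp.read_bytes()).hexdigest()
        (out / "run.log").write_text("\n".join(self.log) + "\n")
        (out / "checksums.json").write_text(json.dumps(checksums, indent=2, sort_keys=True))
        return checksums


def _jsonify(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def _stage(log: list, name: str, fn, *args, **kwargs):
    log.append(f"stage {name}: start")
    try:
        out = fn(*args, **kwargs)
    except Exception as exc:
        raise RuntimeError(f"stage '{name}' failed: {exc}") from exc
    log.append(f"stage {name}: ok")
    return out


# ---------------------------------------------------------------------------
# synthetic study
# ---------------------------------------------------------------------------

def run_synthetic_study(config: StudyConfig | None = None) -> StudyReport:
    """Generate sessions, label states, run the full analysis battery.

    The report contains sections: labels, peri_onset_pupil, lagged_change,
    matched_controls, phase_events, tuning, population (decoded_p / scatter /
    speed per trial), plus summary entries for phase statistics, quantile
    curves, mediation, and ground-truth recovery.
    """
    cfg = (config or StudyConfig()).resolved()
    rng = np.random.default_rng(cfg.seed)
    session_seeds = rng.integers(0, 2**31 - 1, size=cfg.n_sessions)
    report = StudyReport()
    log = report.log

    sessions = _stage(
        log, "generate",
        lambda: [
            synth.generate_session(
                bandit=cfg.bandit, agent=cfg.agent, pupil=cfg.pupil, neural=cfg.neural,
                seed=int(session_seeds[i]), session_id=i,
            )
            for i in range(cfg.n_sessions)
        ],
    )
    trials = pd.concat([s.trials for s in sessions], ignore_index=True)
    counts = [s.counts for s in sessions]
    binned = [s.binned_counts for s in sessions]
    truth = {
        "states": np.concatenate([s.ground_truth["states"] for s in sessions]),
        "onsets": np.concatenate([s.ground_truth["onsets"] for s in sessions]),
    }
    report_core = _run_battery(cfg, trials, counts, binned, report)

    # ground-truth recovery
    lab = report.tables["labels"]
    rec_rows = []
    for i, s in enumerate(sessions):
        m = lab["session"] == i
        st = lab.loc[m, "state"].to_numpy()
        rl = lab.loc[m, "rl_explore"].to_numpy().astype(bool)
        ts = s.ground_truth["states"]
        fit_pe = report.summary["hmm_fits"][i]["p_stay_explore"]
        fit_px = report.summary["hmm_fits"][i]["p_stay_exploit"]
        onset_true = s.ground_truth["onsets"]
        onset_hat = lab.loc[m, "is_onset"].to_numpy().astype(bool)
        hits = int(np.sum(onset_true & onset_hat))
        rec_rows.append(
            {
                "session": i,
                "state_accuracy": float(np.mean((st == EXPLORE) == (ts == EXPLORE))),
                "rl_label_accuracy": float(np.mean(rl == (ts == EXPLORE))),
                "p_stay_explore_true": cfg.agent.p_stay_explore,
                "p_stay_explore_fit": fit_pe,
                "p_stay_exploit_true": cfg.agent.p_stay_exploit,
                "p_stay_exploit_fit": fit_px,
                "onset_recall": hits / max(int(onset_true.sum()), 1),
                "onset_precision": hits / max(int(onset_hat.sum()), 1),
            }
        )
    recovery = pd.DataFrame(rec_rows)
    report.tables["recovery"] = recovery
    report.summary["recovery"] = {
        "mean_state_accuracy": float(recovery["state_accuracy"].mean()),
        "mean_onset_recall": float(recovery["onset_recall"].mean()),
        "p_stay_explore_bias": float(
            (recovery["p_stay_explore_fit"] - recovery["p_stay_explore_true"]).mean()
        ),
        "p_stay_exploit_bias": float(
            (recovery["p_stay_exploit_fit"] - recovery["p_stay_exploit_true"]).mean()
        ),
        "hmm_beats_rl": bool(
            recovery["state_accuracy"].mean() >= recovery["rl_label_accuracy"].mean()
        ),
    }
    log.append("stage recovery: ok")
    if cfg.out_dir:
        report.write(cfg.out_dir)
    return report


# ---------------------------------------------------------------------------
# user-data study
# ---------------------------------------------------------------------------

def validate_trials(trials: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise SchemaError(f"trial table missing required columns: {missing}")


def run_data_study(
    trials: pd.DataFrame | str | Path,
    counts: list | None = None,
    binned: list | None = None,
    config: StudyConfig | None = None,
) -> StudyReport:
    """Run the analysis battery on user data.

    ``trials`` is a table (or CSV path) with columns
    ``session, trial, choice, reward, pupil_z, rt`` (``sacc_vel`` optional);
    ``counts`` is an optional list of per-session (n_trials, n_units) count
    matrices aligned with the session order of the table, ``binned`` an
    optional list of (n_trials, n_units, n_bins) tensors for neural speed.
    """
    cfg = (config or StudyConfig()).resolved()
    if not isinstance(trials, pd.DataFrame):
        trials = pd.read_csv(trials)
    validate_trials(trials)
    if counts is not None:
        sizes = trials.groupby("session", sort=True).size()
        if len(counts) != len(sizes):
            raise SchemaError(
                f"got {len(counts)} count matrices for {len(sizes)} sessions"
            )
        for (sid, n), c in zip(sizes.items(), counts):
            if c.shape[0] != n:
                raise SchemaError(
                    f"session {sid}: {c.shape[0]} count rows but {n} behavioral trials"
                )
    report = StudyReport()
    _run_battery(cfg, trials.copy(), counts, binned, report)
    if cfg.out_dir:
        report.write(cfg.out_dir)
    return report


# ---------------------------------------------------------------------------
# shared battery
# ---------------------------------------------------------------------------

def _run_battery(cfg, trials, counts, binned, report: StudyReport) -> StudyReport:
    log = report.log
    sess_ids = np.sort(trials["session"].unique())
    sessions_col = trials["session"].to_numpy()
    choices = trials["choice"].to_numpy().astype(np.int64)
    rewards = trials["reward"].to_numpy().astype(np.int64)
    n_arms = int(choices.max()) + 1

    # ---- labeling -------------------------------------------------------
    def label():
        states = np.empty(len(trials), dtype=np.int64)
        onset = np.zeros(len(trials), dtype=bool)
        exploit_start = np.zeros(len(trials), dtype=bool)
        rl_flags = np.zeros(len(trials), dtype=bool)
        fits = []
        for sid in sess_ids:
            m = sessions_col == sid
            fit = behavior.fit_explore_hmm(
                choices[m], n_arms=n_arms, n_restarts=cfg.hmm_restarts, seed=cfg.seed
            )
            seq = behavior.viterbi_states(choices[m], fit.params)
            seg = behavior.detect_onsets(seq.states)
            states[m] = seq.states
            onset[m] = seg.onset
            exploit_start[m] = seg.exploit_start
            rw = behavior.fit_rescorla_wagner(
                choices[m], rewards[m], n_arms=n_arms,
                n_starts=cfg.rw_starts, seed=cfg.seed,
            )
            rl_flags[m] = behavior.rl_explore_labels(rw, choices[m])
            fits.append(
                {
                    "session": int(sid),
                    "p_stay_explore": fit.params.p_stay_explore,
                    "p_stay_exploit": fit.params.p_stay_exploit,
                    "log_likelihood": fit.log_likelihood,
                    "degenerate": fit.degenerate,
                    "rw_alpha": rw.alpha,
                    "rw_beta": rw.beta,
                }
            )
        return states, onset, exploit_start, rl_flags, fits

    states, onset, exploit_start, rl_flags, fits = _stage(log, "labels", label)
    labels = trials.copy()
    labels["state"] = states
    labels["is_explore"] = (states == EXPLORE).astype(int)
    labels["is_onset"] = onset.astype(int)
    labels["is_exploit_start"] = exploit_start.astype(int)
    labels["rl_explore"] = rl_flags.astype(int)
    report.tables["labels"] = labels
    report.summary["hmm_fits"] = fits
    is_explore = states == EXPLORE

    # ---- pupil preprocessing -------------------------------------------
    series = _stage(
        log, "preprocess_pupil",
        pupil_mod.preprocess_pupil, trials["pupil_z"].to_numpy(), None, sessions_col,
    )
    pz = np.where(series.valid, series.values, 0.0)  # masked trials neutralized
    report.summary["pupil_exclusions"] = {
        "n_invalid": int((~series.valid).sum()),
        "fraction": float((~series.valid).mean()),
    }
    log.append(f"pupil exclusions: {int((~series.valid).sum())}/{len(series.valid)}")

    # ---- peri-onset pupil ----------------------------------------------
    events = np.flatnonzero(onset)
    peri = _stage(
        log, "peri_onset_pupil",
        pupil_mod.peri_event_matrix, pz, events, cfg.peri_window, sessions_col, states,
    )
    report.tables["peri_onset_pupil"] = pd.DataFrame(
        {"lag": peri.lags, "mean": peri.mean, "sem": peri.sem, "n": peri.n_per_lag}
    )

    # ---- lagged change --------------------------------------------------
    def lagged():
        frames = []
        for sid in sess_ids:
            m = sessions_col == sid
            df = pupil_mod.lagged_pupil_change(pz[m], states[m])
            df.insert(0, "session", sid)
            frames.append(df)
        return pd.concat(frames, ignore_index=True)

    lag_df = _stage(log, "lagged_change", lagged)
    report.tables["lagged_change"] = lag_df
    if len(lag_df):
        keep = lag_df[~lag_df["crossed"]]
        if len(keep) > 2 and keep["lag"].nunique() > 1:
            fit = stats_mod.glm_session_dummies(
                keep["delta"], keep["lag"], keep["session"]
            )
            report.summary["lagged_change_slope"] = fit.to_record("x1")

    # ---- matched rewards + phases --------------------------------------
    def matched():
        rows = []
        onset_phases = []
        control_phases = []
        phases = pupil_mod.morlet_phase(
            pz, cfg.wavelet_period, cfg.wavelet_cycles, sessions_col
        )
        for sid in sess_ids:
            m = sessions_col == sid
            idx = np.flatnonzero(m)
            ms = pupil_mod.match_reward_sequences(
                states[m], rewards[m], k=cfg.match_k, min_matches=cfg.min_matches
            )
            for o, ctrls in zip(ms.onset_indices, ms.controls):
                rows.append({"session": sid, "onset_trial": int(o), "n_controls": len(ctrls)})
                g = idx[o]
                if phases.edge_mask[g]:
                    onset_phases.append(phases.phase[g])
                for w in ctrls:
                    g = idx[w + cfg.match_k - 1] + 1  # would-be onset position
                    if g < len(phases.phase) and sessions_col[g] == sid and phases.edge_mask[g]:
                        control_phases.append(phases.phase[g])
        return pd.DataFrame(rows), np.asarray(onset_phases), np.asarray(control_phases)

    match_df, onset_phases, control_phases = _stage(log, "matched_controls", matched)
    report.tables["matched_controls"] = match_df

    phase_rows = [("onset", p) for p in onset_phases] + [
        ("control", p) for p in control_phases
    ]
    report.tables["phase_events"] = pd.DataFrame(phase_rows, columns=["event", "phase"])

    def phase_stats():
        out = {}
        if len(onset_phases) >= 10:
            res = pupil_mod.phase_locking_stats(
                onset_phases, n_boot=cfg.n_boot, seed=cfg.seed
            )
            out["onset"] = {
                "n": res.n,
                "mean_angle_deg": float(np.degrees(res.mean_angle) % 360),
                "resultant_length": res.resultant_length,
                "p_hodges_ajne": res.p_hodges_ajne,
                "null_mean": res.null_mean,
                "null_ci": list(res.null_ci),
                "p_boot": res.p_boot,
            }
        if len(onset_phases) >= 10 and len(control_phases) >= 10:
            u2, p = pupil_mod.compare_phase_distributions(
                onset_phases, control_phases, n_perm=200, seed=cfg.seed
            )
            out["onset_vs_control"] = {"watson_u2": u2, "p_perm": p}
        return out

    report.summary["phase_stats"] = _stage(log, "phase_stats", phase_stats)

    # ---- quantile curves ------------------------------------------------
    def quantiles():
        out = {}
        for name, outcome in (("explore", is_explore.astype(float)),
                              ("onset", onset.astype(float))):
            qc = pupil_mod.quantile_response_curve(
                pz, outcome, sessions_col, n_quantiles=cfg.n_quantiles
            )
            out[name] = {
                "beta1_linear": qc.linear.to_record("x1"),
                "beta2_quadratic": qc.quadratic.to_record("x1_sq"),
                "aic_weight_linear": qc.aic_weights[0],
                "aic_weight_quadratic": qc.aic_weights[1],
                "delta_aic": qc.delta_aic,
            }
        return out

    report.summary["quantile_curves"] = _stage(log, "quantile_curves", quantiles)

    # ---- neural battery -------------------------------------------------
    if counts is not None:
        def neural_battery():
            frames = []
            tuning_frames = []
            for i, sid in enumerate(sess_ids):
                m = sessions_col == sid
                tensor = neural.prepare_population(counts[i])
                sub = neural.fit_choice_subspace(tensor, choices[m])
                dec = neural.decode_choice_probability(tensor, sub, choices[m])
                proj = sub.project(tensor.counts[:, tensor.included])
                sc = neural.scatter_index(proj, choices[m])
                if binned is not None:
                    speed = neural.neural_speed(
                        binned[i][:, tensor.included, :], sub
                    )
                else:
                    speed = np.full(int(m.sum()), np.nan)
                frames.append(
                    pd.DataFrame(
                        {
                            "session": sid,
                            "trial": trials.loc[m, "trial"].to_numpy(),
                            "decoded_p": dec.p_choice,
                            "scatter": sc.scatter,
                            "speed": speed,
                            "pupil_z": pz[m],
                            "is_explore": is_explore[m].astype(int),
                        }
                    )
                )
                tu, _ = neural.unit_tuning_glm(
                    tensor.rates[:, tensor.included], choices[m], pz[m]
                )
                tu.insert(0, "session", sid)
                tuning_frames.append(tu)
            return pd.concat(frames, ignore_index=True), pd.concat(
                tuning_frames, ignore_index=True
            )

        pop, tuning = _stage(log, "neural", neural_battery)
        report.tables["population"] = pop
        report.tables["tuning"] = tuning
        report.summary["tuning_counts"] = {
            "n_units": int(len(tuning)),
            "pct_choice_tuned": float(100 * tuning["sig_choice"].mean()),
            "pct_pupil_modulated": float(100 * tuning["sig_pupil"].mean()),
            "pct_interaction": float(100 * tuning["sig_interaction"].mean()),
        }

        def pop_glms():
            out = {}
            exploit = pop["is_explore"] == 0
            for name in ("decoded_p", "scatter", "speed"):
                y = pop[name]
                ok = ~y.isna()
                if ok.sum() < 10:
                    continue
                out[name + "_vs_pupil"] = stats_mod.glm_session_dummies(
                    y[ok], pop.loc[ok, "pupil_z"], pop.loc[ok, "session"]
                ).to_record("x1")
                okx = ok & exploit
                if okx.sum() >= 10:
                    out[name + "_vs_pupil_exploit_only"] = stats_mod.glm_session_dummies(
                        y[okx], pop.loc[okx, "pupil_z"], pop.loc[okx, "session"]
                    ).to_record("x1")
            return out

        report.summary["population_glms"] = _stage(log, "population_glms", pop_glms)

        # ---- mediation: pupil(t-1) -> scatter(t-1) -> onset(t) ----------
        def mediation():
            x_, m_, y_, s_ = [], [], [], []
            for sid in sess_ids:
                sel = pop["session"] == sid
                p_ = pop.loc[sel, "pupil_z"].to_numpy()
                sc_ = pop.loc[sel, "scatter"].to_numpy()
                on_ = onset[sessions_col == sid]
                ok = ~np.isnan(sc_[:-1])
                x_.append(p_[:-1][ok])
                m_.append(sc_[:-1][ok])
                y_.append(on_[1:][ok].astype(float))
                s_.append(np.full(int(ok.sum()), sid))
            res = stats_mod.mediation_sobel(
                np.concatenate(x_), np.concatenate(m_), np.concatenate(y_),
                np.concatenate(s_),
            )
            return {
                "c": res.c, "a": res.a, "b": res.b, "c_prime": res.c_prime,
                "ab": res.ab, "sobel_z": res.sobel_z, "sobel_p": res.sobel_p,
                "n": res.n,
            }

        report.summary["mediation_scatter"] = _stage(log, "mediation", mediation)
    return report
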