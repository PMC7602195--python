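"""End-to-end experiment orchestration.

One config describes a cohort of synthetic participants (latency jitter
varying across them), the classifier x channel-set combinations to run, and
the CBLE shift grid.  ``run_experiment`` simulates every participant,
trains on the first sentence of the first session, decodes the remaining
sentences, estimates per-trial latencies, and assembles the three result
surfaces: the blocked accuracy comparison, the vCBLE table, and the
leave-one-participant-out accuracy prediction.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import cble as cble_mod
from . import classifiers as clf_mod
from .preprocess import bandpass, downsample_epochs, epoch, select_channels
from .simulate import ContinuousSession, SimConfig, synthesize_session
from .speller import accuracy_per_sentence, decode, normalize_text
from .stats import AccuracyTable, ComparisonReport, compare_methods

__all__ = [
    "ExperimentConfig",
    "ExperimentResult",
    "run_experiment",
    "cohort_config",
    "write_results",
]

logger = logging.getLogger(__name__)

CLASSIFIERS = ("ls", "swlda", "sae")
CHANNEL_SETS = ("all", "selected")


@dataclass
class ExperimentConfig:
    """Cohort definition plus method and CBLE settings."""

    participants: list[SimConfig]
    #: (classifier, channel set) pairs, e.g. ("swlda", "all"), ("ls", "selected")
    methods: list[tuple[str, str]] = field(
        default_factory=lambda: [(c, "all") for c in CLASSIFIERS]
    )
    n_sessions: int = 1
    n_select: int = 32
    shift_limit_ms: float = 100.0
    shift_step_ms: float = 10.0
    sae_hidden: int = 200
    sae_lambda: float = 0.004
    sae_beta: float = 4.0
    sae_rho: float = 0.05
    sae_max_iter: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        for c, ch in self.methods:
            if c not in CLASSIFIERS or ch not in CHANNEL_SETS:
                raise ValueError(f"unknown method {(c, ch)!r}")

    def method_name(self, classifier: str, channels: str) -> str:
        n = self.n_select if channels == "selected" else self.participants[0].n_channels
        return f"{classifier.upper()}({n})"


@dataclass
class ExperimentResult:
    accuracy_table: AccuracyTable  # percent, blocks = participant x sentence
    participant_accuracy: dict[str, np.ndarray]  # method -> percent per participant
    vcble: dict[str, np.ndarray]  # method -> ms^2 per participant
    cble_results: dict[tuple[str, str], cble_mod.CbleResult]
    true_latency_by_participant: dict[str, np.ndarray]  # truth for analyzed trials
    comparison: ComparisonReport | None
    predictions: dict[str, cble_mod.AccuracyPrediction | None]
    participant_ids: list[str]
    method_names: list[str]


def _derived_seed(*parts: int) -> int:
    return int(np.random.SeedSequence(parts).generate_state(1)[0] % (2**31))


def _fit(classifier: str, fm, cfg: ExperimentConfig, seed: int):
    if classifier == "ls":
        return clf_mod.fit_ls(fm)
    if classifier == "swlda":
        return clf_mod.fit_swlda(fm)
    return clf_mod.fit_sae(
        fm,
        hidden=cfg.sae_hidden,
        lam=cfg.sae_lambda,
        beta=cfg.sae_beta,
        rho=cfg.sae_rho,
        max_iter=cfg.sae_max_iter,
        seed=seed,
        dtype=np.float32,  # halves training time; scoring stays float64
    )


def run_experiment(config: ExperimentConfig) -> ExperimentResult:
    """Run the full cohort experiment; deterministic for a fixed config."""
    method_names = [config.method_name(c, ch) for c, ch in config.methods]
    pids = [f"P{i + 1:02d}" for i in range(len(config.participants))]
    grid = cble_mod.default_shift_grid(config.shift_limit_ms, config.shift_step_ms)

    blocks: list[str] = []
    block_acc: dict[str, list[float]] = {m: [] for m in method_names}
    part_acc: dict[str, list[float]] = {m: [] for m in method_names}
    vcble: dict[str, list[float]] = {m: [] for m in method_names}
    cble_results: dict[tuple[str, str], cble_mod.CbleResult] = {}
    truth_latency: dict[str, np.ndarray] = {}

    for p_idx, (pid, sim_cfg) in enumerate(zip(pids, config.participants)):
        t0 = time.perf_counter()
        sessions: list[ContinuousSession] = []
        for s_idx in range(config.n_sessions):
            s_cfg = replace(
                sim_cfg, rng_seed=_derived_seed(config.seed, sim_cfg.rng_seed, s_idx)
            )
            sessions.append(bandpass(synthesize_session(s_cfg)))
        epoch_sets = [epoch(s) for s in sessions]

        # training data: first sentence of the first session only
        train_sentence_chars = len(normalize_text(sim_cfg.sentences[0]))
        train_mask = epoch_sets[0].char_index < train_sentence_chars
        train_epochs = dataclasses.replace(
            epoch_sets[0],
            data=epoch_sets[0].data[train_mask],
            is_target=epoch_sets[0].is_target[train_mask],
            stim_code=epoch_sets[0].stim_code[train_mask],
            char_index=epoch_sets[0].char_index[train_mask],
            sequence_index=epoch_sets[0].sequence_index[train_mask],
        )

        channel_sets: dict[str, list[str]] = {"all": list(sessions[0].channel_labels)}
        if any(ch == "selected" for _, ch in config.methods):
            channel_sets["selected"] = select_channels(train_epochs, config.n_select)

        # features depend only on the channel set, not the classifier: compute once
        used = {ch for _, ch in config.methods}
        fm_train = {ch: downsample_epochs(train_epochs.select(channel_sets[ch])) for ch in used}
        fm_test = {
            ch: [downsample_epochs(eps.select(channel_sets[ch])) for eps in epoch_sets]
            for ch in used
        }

        # truth latencies of the analyzed (test, target) trials, per session
        truth_parts = []
        test_event_idx: list[np.ndarray] = []
        for s_idx, sess in enumerate(sessions):
            tgt = sess.target_event_indices()
            if s_idx == 0:
                keep = np.array(
                    [sess.events[i].char_index >= train_sentence_chars for i in tgt]
                )
                tgt = tgt[keep]
            test_event_idx.append(tgt)
            truth_parts.append(sess.true_latency_ms[tgt])
        truth_latency[pid] = np.concatenate(truth_parts)

        # shifted-epoch features are classifier independent: one stack per
        # channel set and session, scored by every model
        cble_stacks = {
            ch: [
                cble_mod.shifted_feature_stack(
                    sess, channel_sets[ch], grid, tgt
                )
                for sess, tgt in zip(sessions, test_event_idx)
            ]
            for ch in used
        }

        for (classifier, chset), mname in zip(config.methods, method_names):
            labels = channel_sets[chset]
            model = _fit(classifier, fm_train[chset], config, _derived_seed(config.seed, p_idx))

            # decode every test sentence
            n_correct = 0
            n_total = 0
            for s_idx, (sess, fm) in enumerate(zip(sessions, fm_test[chset])):
                scores = model.score(fm.X)
                sentences = np.unique(sess.sentence_of_char)
                for snt in sentences:
                    if s_idx == 0 and snt == 0:
                        continue  # training sentence
                    mask = sess.sentence_of_char[fm.char_index] == snt
                    chars = "".join(
                        sess.char_labels[i]
                        for i in range(len(sess.char_labels))
                        if sess.sentence_of_char[i] == snt
                    )
                    res = decode(
                        scores[mask],
                        fm.stim_code[mask],
                        fm.char_index[mask],
                        fm.sequence_index[mask],
                        true_chars=chars,
                    )
                    blk = f"{pid}/s{s_idx}/snt{snt}"
                    if blk not in blocks:
                        blocks.append(blk)
                    block_acc[mname].append(100.0 * res.accuracy)
                    n_correct += round(res.accuracy * len(chars))
                    n_total += len(chars)

            # CBLE over all test target trials
            shifts = []
            for sess, tgt, stack in zip(sessions, test_event_idx, cble_stacks[chset]):
                cres = cble_mod.estimate_latencies(
                    model,
                    sess,
                    participant_id=pid,
                    feature_stack=stack,
                )
                shifts.append(cres.per_trial_shift)
            all_shifts = np.concatenate(shifts)
            cble_results[(pid, mname)] = cble_mod.CbleResult(
                per_trial_shift=all_shifts,
                shift_grid=grid,
                vcble=cble_mod.vcble_of(all_shifts),
                event_indices=np.concatenate(test_event_idx),
                participant_id=pid,
                classifier_name=mname,
            )
            vcble[mname].append(cble_results[(pid, mname)].vcble)
            part_acc[mname].append(100.0 * n_correct / n_total)
        logger.info("%s finished in %.1f s", pid, time.perf_counter() - t0)

    table = AccuracyTable(
        np.column_stack([block_acc[m] for m in method_names]),
        method_names=method_names,
        block_ids=blocks,
    )
    comparison = None
    if len(method_names) >= 2:
        comparison = compare_methods(table)

    predictions: dict[str, cble_mod.AccuracyPrediction | None] = {}
    for m in method_names:
        v = np.asarray(vcble[m])
        a = np.asarray(part_acc[m])
        try:
            predictions[m] = cble_mod.predict_accuracy_loo(v, a)
        except ValueError as exc:
            logger.warning("accuracy prediction skipped for %s: %s", m, exc)
            predictions[m] = None

    return ExperimentResult(
        accuracy_table=table,
        participant_accuracy={m: np.asarray(part_acc[m]) for m in method_names},
        vcble={m: np.asarray(vcble[m]) for m in method_names},
        cble_results=cble_results,
        true_latency_by_participant=truth_latency,
        comparison=comparison,
        predictions=predictions,
        participant_ids=pids,
        method_names=method_names,
    )


def cohort_config(
    n_participants: int = 20,
    jitter_range_ms: tuple[float, float] = (0.0, 150.0),
    seed: int = 0,
    sentences: tuple[str, ...] = ("PHONE1", "QUICK2", "BROWN3", "JUMPS4", "FLAME5"),
    methods: list[tuple[str, str]] | None = None,
    **sim_overrides,
) -> ExperimentConfig:
    """Cohort whose participants differ only in P300 latency jitter.

    Jitter standard deviations are drawn uniformly from ``jitter_range_ms``.
    Sentences default to a scaled-down session (6 characters each) so a full
    three-classifier cohort fits a single-CPU time budget; all recording
    parameters keep their defaults.
    """
    rng = np.random.default_rng(seed)
    jitters = rng.uniform(*jitter_range_ms, size=n_participants)
    participants = [
        SimConfig(
            sentences=sentences,
            p300_jitter_sd_ms=float(j),
            rng_seed=_derived_seed(seed, i),
            **sim_overrides,
        )
        for i, j in enumerate(jitters)
    ]
    kwargs = {}
    if methods is not None:
        kwargs["methods"] = methods
    return ExperimentConfig(participants=participants, seed=seed, **kwargs)


def write_results(result: ExperimentResult, out_dir: str | Path) -> None:
    """Persist the result bundle as TSV + JSON files under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.accuracy_table.to_dataframe().to_csv(out / "accuracy_table.tsv", sep="\t")

    if result.comparison is not None:
        c = result.comparison
        (out / "comparison.json").write_text(
            json.dumps(
                {
                    "friedman_stat": c.friedman_stat,
                    "friedman_p": c.friedman_p,
                    "mean_ranks": c.mean_ranks.tolist(),
                    "rank_ci_halfwidth": c.rank_ci_halfwidth,
                    "rank_significant": c.rank_significant.tolist(),
                    "wilcoxon_adjusted_p": c.wilcoxon_adjusted_p.tolist(),
                    "method_names": c.method_names,
                    "alpha": c.alpha,
                },
                indent=2,
            )
        )

    cble_payload = {
        f"{pid}:{m}": {
            "per_trial_shift_ms": r.per_trial_shift.tolist(),
            "vcble_ms2": r.vcble,
        }
        for (pid, m), r in result.cble_results.items()
    }
    (out / "cble.json").write_text(json.dumps(cble_payload, indent=2))

    pred_payload = {}
    for m, p in result.predictions.items():
        if p is None:
            pred_payload[m] = None
            continue
        pred_payload[m] = {
            "vcble_ms2": p.vcble.tolist(),
            "true_accuracy_pct": p.true_accuracy.tolist(),
            "predicted_accuracy_pct": p.predicted_accuracy.tolist(),
            "rmse_pct": p.rmse,
            "r_squared": p.r_squared,
            "pearson_r": p.pearson_r,
            "pearson_p": p.pearson_p,
        }
    (out / "prediction.json").write_text(json.dumps(pred_payload, indent=2))
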