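"""End-to-end pipeline orchestration and configuration.

`PipelineConfig` gathers every stage's parameters with the reference
defaults; `run_pipeline` executes event marking -> SSP -> notch -> FIR
low-pass -> 0.3 s interception -> power screening -> neighborhood-correlation
enhancement -> energy topomaps -> train/evaluate, recording stage counts and
parameters so a run is reproducible from (config, seed) alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import preprocessing as pp
from .enhancement import enhance_trial, trial_energy
from .geometry import DEFAULT_RADIUS, build_neighbourhoods, project_to_plane
from .recognition import (
    ClassifierSpec,
    LabeledImages,
    evaluate,
    split_dataset,
    train_classifier,
)
from .recording import Recording
from .synthmeg import (
    SimulatedSession,
    SynthScenario,
    segment_noise,
    simulate_noise_session,
    simulate_session,
)
from .topomap import TopomapRenderer, write_image_dataset

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All stage parameters, with the reference defaults."""

    scenario: SynthScenario = field(default_factory=SynthScenario)
    classifier: ClassifierSpec = field(default_factory=ClassifierSpec)
    # preprocessing
    notch_freqs: tuple = (10.0, 11.0, 20.0, 21.0)
    notch_bandwidth: float = 2.0
    fir_cutoff: float = 40.0
    fir_stopband_atten: float = 60.0
    line_freqs: tuple = (60.0, 120.0, 180.0)
    ssp_window: float = 0.2
    ssp_components: int = 1
    stim_threshold_frac: float = 0.5
    stim_refractory: float = 0.5
    # interception / screening
    trial_duration: float = 0.3
    screening_k: float = 10.0
    # enhancement
    radius: float = DEFAULT_RADIUS
    corr_threshold: float = 0.8
    enhance_mode: str = "n_minus_1"
    # imaging
    image_size: int = 224
    colormap: str = "viridis"
    # experiment layout
    n_noise_train: int = 200
    n_noise_test: int = 200
    test_n_stimuli: int = 199
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["scenario"]["sources"] = [
            [list(s[0]), list(s[1]), s[2]] for s in self.scenario.sources
        ]
        d["classifier"]["class_labels"] = list(self.classifier.class_labels)
        return d

    @staticmethod
    def from_dict(d: dict) -> "PipelineConfig":
        d = dict(d)
        known = {f.name for f in dataclasses.fields(PipelineConfig)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "scenario" in d and isinstance(d["scenario"], dict):
            sd = dict(d["scenario"])
            s_known = {f.name for f in dataclasses.fields(SynthScenario)}
            s_unknown = set(sd) - s_known
            if s_unknown:
                raise ValueError(f"unknown config keys: scenario.{sorted(s_unknown)}")
            if "sources" in sd:
                sd["sources"] = tuple(
                    (tuple(s[0]), tuple(s[1]), float(s[2])) for s in sd["sources"]
                )
            d["scenario"] = SynthScenario(**sd)
        if "classifier" in d and isinstance(d["classifier"], dict):
            cd = dict(d["classifier"])
            c_known = {f.name for f in dataclasses.fields(ClassifierSpec)}
            c_unknown = set(cd) - c_known
            if c_unknown:
                raise ValueError(f"unknown config keys: classifier.{sorted(c_unknown)}")
            if "class_labels" in cd:
                cd["class_labels"] = tuple(cd["class_labels"])
            d["classifier"] = ClassifierSpec(**cd)
        for key in ("notch_freqs", "line_freqs"):
            if key in d:
                d[key] = tuple(d[key])
        return PipelineConfig(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @staticmethod
    def from_yaml(path) -> "PipelineConfig":
        with open(path) as fh:
            return PipelineConfig.from_dict(yaml.safe_load(fh))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha1(blob).hexdigest()[:12]


# ---------------------------------------------------------------------------
# stage helpers
# ---------------------------------------------------------------------------

def simulate_experiment(config: PipelineConfig):
    """Simulate the training session, the testing session and the noise room.

    The testing session differs by its stimulus count and seed; the noise
    session shares the training session's noise floor.
    """
    scn = config.scenario
    train_session = simulate_session(scn)
    test_scn = dataclasses.replace(
        scn, n_stimuli=config.test_n_stimuli, seed=scn.seed + 1
    )
    test_session = simulate_session(test_scn)
    noise_rec = simulate_noise_session(scn)
    return train_session, test_session, noise_rec


def preprocess_session(rec: Recording, config: PipelineConfig):
    """Event marking + SSP + filters for a subject session.

    Returns the cleaned recording, the detected stimulus events and the
    detected artifact events.
    """
    stim_events = pp.detect_stimulus_events(
        rec.channel("audio"), rec.rate,
        threshold_frac=config.stim_threshold_frac,
        refractory=config.stim_refractory,
    )
    artifact_events = pp.detect_artifact_events(
        rec.channel("eog_v"), rec.channel("eog_h"), rec.channel("ecg"), rec.rate
    )
    projs = []
    for kind in ("blink", "cardiac"):
        sel = artifact_events.of_kind(kind)
        if sel.size:
            ev = pp.EventList(times=sel, kinds=[kind] * sel.size)
            projs.append(
                pp.compute_ssp_projectors(
                    rec, ev, window=config.ssp_window, n_components=config.ssp_components
                )
            )
    cleaned = pp.apply_ssp(rec, pp.stack_projectors(*projs)) if projs else rec
    cleaned = pp.notch_filter(cleaned, config.notch_freqs, config.notch_bandwidth)
    cleaned = pp.lowpass_fir(
        cleaned, config.fir_cutoff, config.fir_stopband_atten, config.line_freqs
    )
    return cleaned, stim_events, artifact_events


def filter_only(rec: Recording, config: PipelineConfig) -> Recording:
    """The filter chain without event marking or SSP (for empty-room noise)."""
    out = pp.notch_filter(rec, config.notch_freqs, config.notch_bandwidth)
    return pp.lowpass_fir(out, config.fir_cutoff, config.fir_stopband_atten, config.line_freqs)


def trials_to_images(trials, renderer: TopomapRenderer, graph, config: PipelineConfig):
    """Enhance each trial, compute normalized energies and render topomaps."""
    images = []
    for tr in trials:
        enh = enhance_trial(tr, graph, threshold=config.corr_threshold, mode=config.enhance_mode)
        energy = trial_energy(enh, normalize=True)
        images.append(renderer.render(energy))
    return images


# ---------------------------------------------------------------------------
# the full experiment
# ---------------------------------------------------------------------------

def run_pipeline(
    config: PipelineConfig,
    train_session: SimulatedSession | None = None,
    test_session: SimulatedSession | None = None,
    noise_rec: Recording | None = None,
    out_dir=None,
    train_model: bool = True,
) -> dict:
    """Run the full experiment; returns a metrics dict.

    Sessions may be supplied (e.g. loaded from disk); missing ones are
    simulated from the config. With ``out_dir`` the image datasets, the model
    checkpoint and the metrics JSON are written there. With
    ``train_model=False`` the run stops after rendering (images only).
    """
    if train_session is None or test_session is None or noise_rec is None:
        sim_train, sim_test, sim_noise = simulate_experiment(config)
        train_session = train_session or sim_train
        test_session = test_session or sim_test
        noise_rec = noise_rec if noise_rec is not None else sim_noise

    array = train_session.array
    graph = build_neighbourhoods(array, config.radius)
    coords = project_to_plane(array)
    renderer = TopomapRenderer(coords, size=config.image_size, cmap=config.colormap)
    metrics: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
    }

    def session_images(session: SimulatedSession, name: str):
        cleaned, stim_events, artifact_events = preprocess_session(
            session.recording, config
        )
        trials = pp.segment_trials(cleaned, stim_events, duration=config.trial_duration)
        kept, rejected = pp.screen_trials(trials, k=config.screening_k)
        metrics["stages"][name] = {
            "stimuli_detected": int(len(stim_events.of_kind("stimulus"))),
            "stimuli_truth": int(len(session.events.of_kind("stimulus"))),
            "artifacts_detected": int(len(artifact_events)),
            "trials_segmented": len(trials),
            "trials_kept": len(kept),
            "trials_rejected": rejected,
        }
        images = trials_to_images([trials[i] for i in kept], renderer, graph, config)
        ids = [trials[i].trial_id for i in kept]
        return images, ids

    train_aef_images, train_aef_ids = session_images(train_session, "train_session")
    test_aef_images, test_aef_ids = session_images(test_session, "test_session")

    noise_clean = filter_only(noise_rec, config)
    noise_trials = segment_noise(
        noise_clean, config.trial_duration, config.n_noise_train + config.n_noise_test
    )
    if len(noise_trials) < config.n_noise_train + config.n_noise_test:
        raise ValueError("noise recording too short for the requested segment counts")
    noise_images = trials_to_images(noise_trials, renderer, graph, config)
    noise_ids = [tr.trial_id for tr in noise_trials]
    metrics["stages"]["noise"] = {"segments": len(noise_trials)}

    ntr = config.n_noise_train
    train_images = train_aef_images + noise_images[:ntr]
    train_labels = ["aef"] * len(train_aef_images) + ["noise"] * ntr
    train_ids = train_aef_ids + noise_ids[:ntr]
    test_images = test_aef_images + noise_images[ntr : ntr + config.n_noise_test]
    test_labels = ["aef"] * len(test_aef_images) + ["noise"] * config.n_noise_test
    test_ids = test_aef_ids + noise_ids[ntr : ntr + config.n_noise_test]
    metrics["stages"]["images"] = {
        "training_source": len(train_images),
        "testing_source": len(test_images),
    }

    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        write_image_dataset(train_images, train_labels, out_dir / "train", train_ids)
        write_image_dataset(test_images, test_labels, out_dir / "test", test_ids)
        config.to_yaml(out_dir / "config.yaml")

    if not train_model:
        if out_dir is not None:
            (out_dir / "metrics.json").write_text(json.dumps(metrics, indent=1))
        return metrics

    train_all = LabeledImages.from_topoimages(train_images, train_labels, train_ids)
    test_all = LabeledImages.from_topoimages(test_images, test_labels, test_ids)
    fit_set, val_set = split_dataset(
        train_all, val_fraction=config.classifier.val_fraction, seed=config.classifier.seed
    )
    metrics["stages"]["split"] = {"train": len(fit_set), "validation": len(val_set)}
    model = train_classifier(fit_set, val_set, config.classifier)
    metrics["training_history"] = model.training_history

    eval_train = evaluate(model, train_all)
    eval_test = evaluate(model, test_all)
    metrics["training_source_accuracy"] = eval_train["accuracy"]
    metrics["testing_source_accuracy"] = eval_test["accuracy"]
    metrics["confusion_training_source"] = eval_train["confusion"]
    metrics["confusion_testing_source"] = eval_test["confusion"]

    if out_dir is not None:
        model.save(out_dir / "model.npz")
        (out_dir / "metrics.json").write_text(json.dumps(metrics, indent=1))
    logger.info(
        "pipeline done: training-source accuracy %.4f, testing-source accuracy %.4f",
        eval_train["accuracy"], eval_test["accuracy"],
    )
    return metrics
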