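"""End-to-end pipeline orchestration with reproducible configuration.

Stage order: simulate -> preprocess -> image -> train -> cluster ->
characterize -> associate. A single global seed is expanded into
independent per-stage seeds through numpy's SeedSequence keyed on the
stage name, so any stage can be re-run in isolation and reproduce its
output. Each run writes a manifest (config hash, seed, per-stage output
checksums) so identical configs yield identical manifests for the
deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import associations, characterize, cluster as clustermod, cohort, imaging, preprocess
from .cae import CAEConfig, build_cae, encode, train_cae

STAGES = ["simulate", "preprocess", "image", "train", "cluster", "characterize", "associate"]

DEFAULT_COVARIATES_ANCOVA = ["age", "sex", "ethnicity", "marital_status", "income_poverty_ratio"]
DEFAULT_CANDIDATE_POOL = DEFAULT_COVARIATES_ANCOVA + [
    "smoking", "alcohol_g_day", "energy_kcal", "sat_fat_g", "caffeine_mg",
    "cvd", "diabetes", "cancer",
]
DEFAULT_MARKERS = [
    "insulin", "triglycerides", "homa_ir", "glucose", "crp",
    "tot_hdl_ratio", "ldl", "waist_cm", "bmi",
]


class StageDependencyError(RuntimeError):
    pass


@dataclass
class RunConfig:
    out_dir: str = "runs/default"
    seed: int = 0
    n_participants: int = 200
    image_side: int = 64
    latent_dim: int = 8
    epochs: int = 30
    batch_size: int = 32
    channels: tuple[int, int, int, int] = (16, 32, 64, 128)
    learning_rate: float = 1e-3
    k: int | None = None  # manual override; None -> automated selection
    k_range: tuple[int, int] = (1, 10)
    n_restarts: int = 10
    balance_fraction: float = 0.1
    referent_profile: int | None = None  # None -> lowest-activity profile
    covariates_ancova: list[str] = field(default_factory=lambda: list(DEFAULT_COVARIATES_ANCOVA))
    candidate_pool: list[str] = field(default_factory=lambda: list(DEFAULT_CANDIDATE_POOL))
    markers: list[str] = field(default_factory=lambda: list(DEFAULT_MARKERS))
    marker_effects: dict = field(default_factory=cohort.default_marker_effects)
    randomize_start_weekday: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls(**data)
        cfg.channels = tuple(cfg.channels)
        cfg.k_range = tuple(cfg.k_range)
        return cfg

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["channels"] = list(self.channels)
        d["k_range"] = list(self.k_range)
        return d


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    ss = np.random.SeedSequence([int(global_seed), zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


class Pipeline:
    def __init__(self, config: RunConfig):
        self.config = config
        self.out = Path(config.out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.manifest: dict = {
            "seed": config.seed,
            "config": config.to_dict(),
            "config_hash": hashlib.sha256(
                json.dumps(config.to_dict(), sort_keys=True).encode()
            ).hexdigest(),
            "stages": {},
            "exclusions": [],
        }

    # ---------------------------------------------------------- stages

    def _require(self, *paths: str) -> None:
        for p in paths:
            if not (self.out / p).exists():
                raise StageDependencyError(f"missing upstream artifact: {self.out / p}")

    def _record(self, stage: str, files: list[str], t0: float) -> None:
        self.manifest["stages"][stage] = {
            "outputs": {f: _sha256(self.out / f) for f in files},
            "seconds": round(time.time() - t0, 3),
        }

    def simulate(self) -> None:
        t0 = time.time()
        cfg = self.config
        ccfg = cohort.CohortConfig(
            n_participants=cfg.n_participants,
            seed=stage_seed(cfg.seed, "simulate"),
            marker_effects=cfg.marker_effects,
            randomize_start_weekday=cfg.randomize_start_weekday,
        )
        traces, labels = cohort.generate_cohort(ccfg)
        covs = cohort.generate_covariates(labels, ccfg, stage_seed(cfg.seed, "covariates"))
        markers = cohort.generate_markers(
            labels, covs, ccfg.marker_effects, stage_seed(cfg.seed, "markers"),
            archetypes=ccfg.archetypes,
        )
        cohort.traces_to_frame(traces).to_csv(self.out / "traces.csv", index=False)
        covs.to_csv(self.out / "covariates.csv", index=False)
        markers.to_csv(self.out / "markers.csv", index=False)
        pd.DataFrame(
            {"participant_id": [t.participant_id for t in traces],
             "archetype": [ccfg.archetypes[l].name for l in labels]}
        ).to_csv(self.out / "truth.csv", index=False)
        self._record("simulate", ["traces.csv", "covariates.csv", "markers.csv", "truth.csv"], t0)

    def preprocess(self) -> None:
        t0 = time.time()
        self._require("traces.csv")
        traces = cohort.traces_from_frame(pd.read_csv(self.out / "traces.csv"))
        metrics: dict[str, preprocess.BoutMetrics] = {}
        series_store = {}
        for trace in traces:
            series, daily, eligible = preprocess.process_trace(trace)
            if not eligible:
                self.manifest["exclusions"].append(
                    {"participant_id": trace.participant_id,
                     "reason": "insufficient_valid_days",
                     "valid_days": int(sum(d.valid for d in daily))}
                )
                continue
            metrics[trace.participant_id] = preprocess.sedentary_bout_metrics(series, daily)
            series_store[trace.participant_id] = (series, daily)
        preprocess.metrics_table(metrics).to_csv(self.out / "metrics.csv", index=False)
        # persist labelled series for the imaging stage
        rows = []
        for pid, (series, daily) in series_store.items():
            valid = {d.weekday for d in daily if d.valid}
            rows.append(pd.DataFrame({
                "participant_id": pid,
                "weekday": series.weekday,
                "minute_of_day": series.minute_of_day,
                "category": series.category,
                "day_valid": np.isin(series.weekday, list(valid)).astype(int),
            }))
        pd.concat(rows, ignore_index=True).to_csv(self.out / "series.csv", index=False)
        self._record("preprocess", ["metrics.csv", "series.csv"], t0)

    def image(self) -> None:
        t0 = time.time()
        self._require("series.csv")
        df = pd.read_csv(self.out / "series.csv")
        img_dir = self.out / "images"
        img_dir.mkdir(exist_ok=True)
        files = []
        mat_rows = {}
        for pid, g in df.groupby("participant_id", sort=True):
            series = preprocess.IntensitySeries(
                participant_id=str(pid),
                weekday=g["weekday"].to_numpy(),
                minute_of_day=g["minute_of_day"].to_numpy(),
                category=np.where(g["day_valid"].to_numpy() == 1,
                                  g["category"].to_numpy(), preprocess.NONWEAR).astype(np.int8),
            )
            matrix = imaging.build_matrix(series, daily=None, valid_only=False)
            mat_rows[str(pid)] = matrix
            image = imaging.render(matrix)
            imaging.save_png(image, img_dir / f"{pid}.png")
            files.append(f"images/{pid}.png")
        np.savez_compressed(
            self.out / "matrices.npz", **{pid: m for pid, m in mat_rows.items()}
        )
        self._record("image", files + ["matrices.npz"], t0)

    def _load_images(self) -> tuple[list[str], np.ndarray]:
        data = np.load(self.out / "matrices.npz")
        pids = sorted(data.files)
        side = self.config.image_side
        imgs = np.stack([
            imaging.prepare_for_model(imaging.render(data[pid]), side) for pid in pids
        ])
        return pids, imgs

    def train(self) -> None:
        t0 = time.time()
        self._require("matrices.npz")
        cfg = self.config
        pids, imgs = self._load_images()
        cae_cfg = CAEConfig(
            input_side=cfg.image_side, channels=cfg.channels, latent_dim=cfg.latent_dim,
            epochs=cfg.epochs, batch_size=cfg.batch_size,
            learning_rate=cfg.learning_rate, seed=stage_seed(cfg.seed, "train"),
        )
        model = build_cae(cae_cfg)
        model, curve = train_cae(model, imgs, cae_cfg)
        latents = encode(model, imgs)
        lat = pd.DataFrame(latents, columns=[f"z{i}" for i in range(latents.shape[1])])
        lat.insert(0, "participant_id", pids)
        lat.to_csv(self.out / "latents.csv", index=False)
        pd.DataFrame({"epoch": range(1, len(curve) + 1), "loss": curve}).to_csv(
            self.out / "learning_curve.csv", index=False
        )
        from .cae import save_model

        save_model(model, self.out / "cae_model.npz")
        self._record("train", ["latents.csv", "learning_curve.csv", "cae_model.npz"], t0)

    def cluster(self) -> None:
        t0 = time.time()
        self._require("latents.csv")
        cfg = self.config
        lat = pd.read_csv(self.out / "latents.csv")
        z = lat.drop(columns="participant_id").to_numpy()
        seed = stage_seed(cfg.seed, "cluster")
        lo, hi = cfg.k_range
        hi = min(hi, len(z))
        solutions, report = clustermod.evaluate_k_range(
            z, range(lo, hi + 1), n_restarts=cfg.n_restarts, seed=seed
        )
        if cfg.k is not None:
            report.chosen_k = cfg.k
            report.notes.append("manual k override")
        else:
            report = clustermod.select_k(report, balance_fraction=cfg.balance_fraction)
        chosen = solutions.get(report.chosen_k) or clustermod.kmeans_pp(
            z, report.chosen_k, n_restarts=cfg.n_restarts, seed=seed
        )
        pd.DataFrame(
            {"participant_id": lat["participant_id"], "profile_id": chosen.assignments}
        ).to_csv(self.out / "assignments.csv", index=False)
        pd.DataFrame(
            {
                "k": report.k_values,
                "inertia": report.inertia,
                "silhouette": [s if s is not None else "" for s in report.silhouette],
                "sizes": [";".join(map(str, s)) for s in report.cluster_sizes],
                "chosen": [int(k == report.chosen_k) for k in report.k_values],
            }
        ).to_csv(self.out / "k_selection.csv", index=False)
        self._record("cluster", ["assignments.csv", "k_selection.csv"], t0)

    def _profile_table(self) -> pd.DataFrame:
        self._require("assignments.csv", "metrics.csv", "covariates.csv", "markers.csv")
        a = pd.read_csv(self.out / "assignments.csv")
        m = pd.read_csv(self.out / "metrics.csv")
        c = pd.read_csv(self.out / "covariates.csv")
        mk = pd.read_csv(self.out / "markers.csv")
        df = a.merge(m, on="participant_id").merge(c, on="participant_id").merge(
            mk, on="participant_id"
        )
        return df.rename(columns={"profile_id": "profile"})

    def referent_profile(self, table: pd.DataFrame) -> int:
        """The least-active profile: lowest mean MVPA + light min/day."""
        if self.config.referent_profile is not None:
            return self.config.referent_profile
        act = table.groupby("profile")[["mvpa_min_per_day", "light_min_per_day"]].mean().sum(axis=1)
        return int(act.idxmin())

    def characterize(self) -> None:
        t0 = time.time()
        table = self._profile_table()
        outcomes = [
            "mvpa_min_per_day", "light_min_per_day", "sedentary_min_per_day",
            "pct_sed_15_30", "pct_sed_ge30", "interruptions_per_sed_hour",
        ]
        rows = []
        for outcome in outcomes:
            sub = table.dropna(subset=[outcome])
            res = characterize.ancova_compare(
                sub, outcome, self.config.covariates_ancova, always_pairwise=True
            )
            for level, (mean, lo, hi) in res.adjusted_means.items():
                rows.append({"outcome": outcome, "profile": level, "adjusted_mean": mean,
                             "ci_low": lo, "ci_high": hi,
                             "overall_F": res.f_statistic, "overall_p": res.p_value})
        pd.DataFrame(rows).to_csv(self.out / "ancova.csv", index=False)

        data = np.load(self.out / "matrices.npz")
        assign = pd.read_csv(self.out / "assignments.csv").set_index("participant_id")
        matrices = {pid: data[pid] for pid in data.files if pid in assign.index}
        heat = characterize.temporal_heatmap(
            matrices, assign.loc[list(matrices)]["profile_id"]
        )
        arrays = {
            f"profile{p}_{behavior}": vec
            for p, behaviors in heat.items() for behavior, vec in behaviors.items()
        }
        np.savez_compressed(self.out / "heatmaps.npz", **arrays)
        self._record("characterize", ["ancova.csv", "heatmaps.npz"], t0)

    def associate(self) -> None:
        t0 = time.time()
        table = self._profile_table()
        referent = self.referent_profile(table)
        results = []
        for marker in self.config.markers:
            log_scale = associations.choose_transform(marker, table[marker].to_numpy())
            retained = associations.backward_eliminate(
                table, marker, list(self.config.candidate_pool),
                referent=referent, log_outcome=log_scale,
            )
            results.append(
                associations.fit_association(
                    table, marker, referent, retained, log_scale=log_scale
                )
            )
        associations.association_table(results).to_csv(
            self.out / "associations.csv", index=False
        )
        self._record("associate", ["associations.csv"], t0)

    # ------------------------------------------------------------- run

    def run(self, stages: list[str] | None = None) -> dict:
        stages = stages or STAGES
        unknown = set(stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        for stage in STAGES:
            if stage in stages:
                getattr(self, stage)()
        with open(self.out / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=2, sort_keys=True)
        return self.manifest


def run(config: RunConfig, stages: list[str] | None = None) -> dict:
    return Pipeline(config).run(stages)
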