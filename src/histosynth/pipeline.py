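"""End-to-end orchestration: fixtures -> autoencoder -> latents -> clustering
sweep -> validity selection -> conditional diffusion -> sampling -> evaluation.

Each stage writes its artifacts under the run directory together with a
``<stage>.done.json`` marker recording the configuration hash, so a rerun
with the same configuration resumes after the last completed stage and a
changed configuration invalidates everything downstream. Every random draw
descends from the single run seed.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .clustering import (
    ClusteringConfig,
    ClusterHead,
    augment_tile,
    hard_labels,
    latent_features,
    train_clustering,
)
from .data import TileDataset
from .dataio import read_tiles, write_tiles
from .diffusion import (
    DiffusionConfig,
    DenoiserUNet,
    LatentNormalizer,
    TrainPhase,
    conditional_fidelity,
    desk_diffusion_config,
    desk_phases,
    default_phases,
    make_linear_schedule,
    sample_batch,
    train_ldm,
)
from .errors import InvalidArgument
from .metrics import SimilarityReport, evaluate_generation, select_best_cluster_set
from .synthetic import generate_dataset
from .validity import IndexReport, LabeledPointSet, compute_index_report, consensus_select_k
from .vqgan import VQGAN, VQGANConfig, desk_vqgan_config, load_vqgan, quantize, train_vqgan

__all__ = [
    "PipelineConfig",
    "RunManifest",
    "desk_pipeline_config",
    "paper_pipeline_config",
    "run_pipeline",
    "report",
]


@dataclass
class PipelineConfig:
    """Everything a run needs; ``scale`` is 'desk' (CPU minutes) or 'paper'."""

    out_dir: str
    scale: str = "desk"
    seed: int = 0
    tile_size: int = 32
    n_classes: int = 3
    n_per_class: int = 16
    n_test_per_class: int = 4
    preset_indices: tuple[int, ...] | None = (0, 6, 2)
    k_min: int = 2
    k_max: int = 5
    feature_mode: str = "mean-pool"
    n_fidelity_per_cluster: int = 10
    vqgan: VQGANConfig = field(default_factory=desk_vqgan_config)
    diffusion: DiffusionConfig = field(default_factory=desk_diffusion_config)
    phases: list[TrainPhase] = field(default_factory=desk_phases)
    clustering: ClusteringConfig = field(default_factory=ClusteringConfig)

    def config_hash(self) -> str:
        payload = json.dumps(
            {k: v for k, v in asdict(self).items() if k != "out_dir"},
            sort_keys=True,
            default=list,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def desk_pipeline_config(out_dir: str, seed: int = 0, **overrides) -> PipelineConfig:
    """The small preset: 3 well-separated phenotypes (dense tumor, empty
    space, red-blood-cell parenchyma), 48 training tiles of size 32, latent
    8x8, T = 50, reduced epochs, k swept over 2..5."""
    cfg = PipelineConfig(
        out_dir=str(out_dir),
        seed=seed,
        vqgan=desk_vqgan_config(seed=seed),
        diffusion=desk_diffusion_config(seed=seed),
        clustering=ClusteringConfig(seed=seed, epochs=500, n_restarts=16),
    )
    for k, v in overrides.items():
        if not hasattr(cfg, k):
            raise InvalidArgument(f"unknown config field {k!r}")
        setattr(cfg, k, v)
    return cfg


def paper_pipeline_config(out_dir: str, seed: int = 0) -> PipelineConfig:
    """The full-scale preset: 128x128 tiles, codebook 128x16 with 32x32
    latents, T = 1000, the three-phase 600/130/70 protocol, k swept 10..16."""
    return PipelineConfig(
        out_dir=str(out_dir),
        scale="paper",
        seed=seed,
        tile_size=128,
        n_classes=14,
        n_per_class=715,  # ~10k training tiles across the preset bank
        n_test_per_class=72,
        preset_indices=None,
        k_min=10,
        k_max=16,
        n_fidelity_per_cluster=100,
        vqgan=VQGANConfig(seed=seed),
        diffusion=DiffusionConfig(seed=seed),
        phases=default_phases(),
        clustering=ClusteringConfig(seed=seed, epochs=600),
    )


@dataclass
class RunManifest:
    """What a run produced: per-stage artifact paths and content hashes."""

    config_hash: str
    seed: int
    version: str
    stages: dict = field(default_factory=dict)
    started: float = 0.0
    finished: float = 0.0

    def save(self, path: Path) -> None:
        path.write_text(json.dumps(asdict(self), indent=2, sort_keys=True))

    @staticmethod
    def load(path: Path) -> "RunManifest":
        return RunManifest(**json.loads(Path(path).read_text()))


def _file_hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


class _StageRunner:
    """Skip-or-run helper: a stage is skipped when its marker matches the
    current configuration hash and all recorded artifacts still exist."""

    def __init__(self, out: Path, cfg_hash: str, manifest: RunManifest):
        self.out = out
        self.cfg_hash = cfg_hash
        self.manifest = manifest

    def done_marker(self, stage: str) -> Path:
        return self.out / f"{stage}.done.json"

    def is_done(self, stage: str) -> bool:
        marker = self.done_marker(stage)
        if not marker.exists():
            return False
        info = json.loads(marker.read_text())
        if info.get("config_hash") != self.cfg_hash:
            return False
        return all(Path(p).exists() for p in info.get("artifacts", []))

    def finish(self, stage: str, artifacts: list[Path]) -> None:
        info = {
            "config_hash": self.cfg_hash,
            "artifacts": [str(p) for p in artifacts],
            "hashes": {p.name: _file_hash(p) for p in artifacts if p.is_file()},
        }
        self.done_marker(stage).write_text(json.dumps(info, indent=2, sort_keys=True))
        self.manifest.stages[stage] = info


def _extract_features(
    model: VQGAN, dataset: TileDataset, mode: str, rng
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Latent views of a dataset needed downstream.

    Returns ``(z_e grids, pooled features, transformed-tile features,
    round-trip features)``. Diffusion trains on the continuous
    pre-quantization grids; clustering consumes pooled quantized features.
    The two augmented feature sets feed the SAT consistency term: one from
    a rotated/translated/rescaled copy of each tile, one from the tile's
    own decode->re-encode round trip, so cluster assignments stay stable
    both under geometric transforms and under the autoencoder loop that
    every generated image passes through before being scored.
    """
    cb = model.codebook
    grids, feats, aug_feats, rt_feats = [], [], [], []
    for tile in dataset.tiles:
        z_e = model.encode(tile)
        q = quantize(z_e, cb)
        grids.append(z_e)
        feats.append(latent_features(q, mode=mode))
        aug = augment_tile(tile.pixels, rng)
        aug_feats.append(latent_features(quantize(model.encode(aug), cb), mode=mode))
        rt = model.decode(q.embedded)
        rt_feats.append(latent_features(quantize(model.encode(rt), cb), mode=mode))
    return np.stack(grids), np.stack(feats), np.stack(aug_feats), np.stack(rt_feats)


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute every stage in order and return the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.config_hash()
    manifest_path = out / "manifest.json"
    manifest = RunManifest(config_hash=cfg_hash, seed=config.seed, version=__version__)
    manifest.started = time.time()
    runner = _StageRunner(out, cfg_hash, manifest)
    (out / "config.json").write_text(
        json.dumps(asdict(config), indent=2, sort_keys=True, default=list)
    )

    # -- stage 1: fixtures ---------------------------------------------------
    train_dir, test_dir = out / "fixtures" / "train", out / "fixtures" / "test"
    if not runner.is_done("fixtures"):
        preset = list(config.preset_indices) if config.preset_indices else None
        train_ds = generate_dataset(
            config.n_classes, config.n_per_class, config.tile_size,
            seed=config.seed, preset_indices=preset, split="train",
        )
        test_ds = generate_dataset(
            config.n_classes, config.n_test_per_class, config.tile_size,
            seed=config.seed + 1, preset_indices=preset, split="test",
        )
        write_tiles(train_ds, train_dir, manifest={"seed": config.seed})
        write_tiles(test_ds, test_dir, manifest={"seed": config.seed + 1})
        runner.finish("fixtures", [train_dir, test_dir])
    else:
        manifest.stages["fixtures"] = json.loads(runner.done_marker("fixtures").read_text())
    train_ds = read_tiles(train_dir)
    test_ds = read_tiles(test_dir)

    # -- stage 2: autoencoder ------------------------------------------------
    vq_dir = out / "vqgan"
    ckpt = vq_dir / "vqgan_checkpoint.npz"
    if not runner.is_done("vqgan"):
        model, _, _ = train_vqgan(train_ds, config.vqgan, out_dir=vq_dir)
        runner.finish("vqgan", [ckpt, vq_dir / "vqgan_losses.csv"])
    else:
        manifest.stages["vqgan"] = json.loads(runner.done_marker("vqgan").read_text())
        model = load_vqgan(ckpt)
    model = load_vqgan(ckpt)  # always evaluate the checkpointed parameters

    # -- stage 3: latent features -------------------------------------------
    lat_path = out / "latents.npz"
    if not runner.is_done("latents"):
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
        grids, feats, aug_feats, rt_feats = _extract_features(
            model, train_ds, config.feature_mode, rng
        )
        np.savez(lat_path, grids=grids, features=feats, augmented=aug_feats,
                 roundtrip=rt_feats,
                 labels=train_ds.true_labels if train_ds.true_labels is not None else np.array([]))
        runner.finish("latents", [lat_path])
    else:
        manifest.stages["latents"] = json.loads(runner.done_marker("latents").read_text())
    with np.load(lat_path) as z:
        grids, feats, aug_feats, rt_feats = (
            z["grids"], z["features"], z["augmented"], z["roundtrip"]
        )
    # SAT pairs for clustering: each tile appears twice, once paired with its
    # transformed copy and once with its autoencoder round trip
    sat_x = np.vstack([feats, feats])
    sat_aug = np.vstack([aug_feats, rt_feats])

    # -- stage 4: clustering sweep ------------------------------------------
    ks = list(range(config.k_min, config.k_max + 1))
    heads: dict[int, ClusterHead] = {}
    assignments: dict[int, np.ndarray] = {}
    sweep_files = []
    for k in ks:
        csv_path = out / f"assignments_k{k}.csv"
        head = ClusterHead(feats.shape[1], k, hidden=config.clustering.hidden,
                           seed=config.clustering.seed + k)
        npz_path = out / f"cluster_head_k{k}.npz"
        if not runner.is_done(f"cluster_k{k}"):
            cl_cfg = ClusteringConfig(**{**asdict(config.clustering), "seed": config.clustering.seed + k})
            head, _, _ = train_clustering(sat_x, k, cl_cfg, augmented_features=sat_aug)
            assign = head.predict(feats)
            state = head.state_dict()
            np.savez(npz_path, mu=head._mu, sigma=head._sigma,
                     **{f"p/{n}": v for n, v in state.items()})
            df = pd.DataFrame(assign.probs, columns=[f"p_{i}" for i in range(k)])
            df.insert(0, "hard_label", hard_labels(assign))
            df.insert(0, "id", train_ds.ids)
            df.to_csv(csv_path, index=False)
            runner.finish(f"cluster_k{k}", [csv_path, npz_path])
        else:
            manifest.stages[f"cluster_k{k}"] = json.loads(runner.done_marker(f"cluster_k{k}").read_text())
            with np.load(npz_path) as z:
                head._mu, head._sigma = z["mu"], z["sigma"]
                head.load_state_dict({n[len("p/"):]: z[n] for n in z.files if n.startswith("p/")})
        heads[k] = head
        assignments[k] = hard_labels(head.predict(feats))
        sweep_files.append(csv_path)

    # -- stage 5: validity indices + consensus k ------------------------------
    validity_csv = out / "validity_indices.csv"
    selection_json = out / "k_selection.json"
    if not runner.is_done("validity"):
        reports = []
        for k in ks:
            labels = assignments[k]
            # clusters can die during MI training; re-map to the occupied set
            uniq = np.unique(labels)
            remap = {c: i for i, c in enumerate(uniq)}
            eff = np.array([remap[c] for c in labels])
            if len(uniq) < 2:
                continue
            ps = LabeledPointSet(feats, eff, len(uniq))
            r = compute_index_report(ps)
            r.k = k
            reports.append(r)
        if len(reports) < 2:
            raise InvalidArgument("fewer than two valid clusterings in the sweep")
        selected_k, winners = consensus_select_k(reports)
        pd.DataFrame([asdict(r) for r in reports]).to_csv(validity_csv, index=False)
        selection_json.write_text(json.dumps(
            {"selected_k": int(selected_k), "winners": winners}, indent=2, sort_keys=True))
        runner.finish("validity", [validity_csv, selection_json])
    else:
        manifest.stages["validity"] = json.loads(runner.done_marker("validity").read_text())
    selected_k = json.loads(selection_json.read_text())["selected_k"]
    cond = assignments[selected_k]
    head = heads[selected_k]

    # -- stage 6: conditional diffusion ---------------------------------------
    ldm_path = out / "ldm_checkpoint.npz"
    losses_csv = out / "ldm_losses.csv"
    n_cond = int(cond.max()) + 1
    def _build_net():
        return DenoiserUNet(
            latent_dim=grids.shape[3], n_clusters=n_cond, T=config.diffusion.T,
            base_channels=config.diffusion.base_channels, n_down=config.diffusion.n_down,
            emb_dim=config.diffusion.emb_dim, seed=config.diffusion.seed,
        )
    normalizer = LatentNormalizer.fit(grids)
    if not runner.is_done("diffusion"):
        net, log = train_ldm(
            normalizer.normalize(grids), cond, config.phases, config.diffusion,
            cluster_head=head, features=feats, augmented_features=aug_feats,
        )
        np.savez(ldm_path, n_clusters=np.array(n_cond),
                 norm_mu=normalizer.mu, norm_sigma=normalizer.sigma,
                 **{f"p/{n}": v for n, v in net.state_dict().items()})
        pd.DataFrame(log).to_csv(losses_csv, index=False)
        runner.finish("diffusion", [ldm_path, losses_csv])
    else:
        manifest.stages["diffusion"] = json.loads(runner.done_marker("diffusion").read_text())
    net = _build_net()
    with np.load(ldm_path) as z:
        net.load_state_dict({n[len("p/"):]: z[n] for n in z.files if n.startswith("p/")})
        normalizer = LatentNormalizer(mu=z["norm_mu"], sigma=z["norm_sigma"])

    # -- stage 7: sampling -----------------------------------------------------
    schedule = make_linear_schedule(
        config.diffusion.T, config.diffusion.beta_start, config.diffusion.beta_end
    )
    gen_dir = out / "generated"
    fid_dir = out / "fidelity_samples"
    latent_hw = grids.shape[1]
    if not runner.is_done("sampling"):
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
        gen = sample_batch(cond, net, schedule, model, rng, latent_hw, normalizer=normalizer)
        write_tiles(gen, gen_dir)
        fid_conds = np.repeat(np.arange(n_cond), config.n_fidelity_per_cluster)
        fid = sample_batch(fid_conds, net, schedule, model, rng, latent_hw, normalizer=normalizer)
        write_tiles(fid, fid_dir, manifest={"intended": fid_conds.tolist()})
        runner.finish("sampling", [gen_dir, fid_dir])
    else:
        manifest.stages["sampling"] = json.loads(runner.done_marker("sampling").read_text())
    gen = read_tiles(gen_dir)
    fid = read_tiles(fid_dir)
    fid_conds = np.array(json.loads((fid_dir / "manifest.json").read_text())["intended"])

    # -- stage 8: evaluation ---------------------------------------------------
    sim_csv = out / "similarity.csv"
    fid_csv = out / "fidelity.csv"
    if not runner.is_done("evaluate"):
        rep = evaluate_generation(gen, train_ds, pairing="by-source", k=selected_k,
                                  window_size=min(11, config.tile_size))
        pd.DataFrame([{
            "k": rep.k, "ssim": rep.ssim_mean, "ms_ssim": rep.ms_ssim_mean,
            "lpips": rep.lpips_mean, "n_pairs": rep.n_pairs,
        }]).to_csv(sim_csv, index=False)
        overall, table = conditional_fidelity(fid, fid_conds, model, head,
                                              feature_mode=config.feature_mode)
        table = pd.concat([table, pd.DataFrame([{
            "cluster": -1, "n": len(fid), "n_correct": int(round(overall * len(fid))),
            "accuracy": overall,
        }])], ignore_index=True)
        table.to_csv(fid_csv, index=False)
        runner.finish("evaluate", [sim_csv, fid_csv])
    else:
        manifest.stages["evaluate"] = json.loads(runner.done_marker("evaluate").read_text())

    manifest.finished = time.time()
    manifest.save(manifest_path)
    return manifest


# -- reporting ------------------------------------------------------------------


def _image_grid(dataset: TileDataset, path: Path, n: int = 8) -> None:
    from PIL import Image

    n = min(n, len(dataset))
    tiles = [np.clip(np.round(t.pixels * 255), 0, 255).astype(np.uint8) for t in dataset.tiles[:n]]
    grid = np.concatenate(tiles, axis=1)
    Image.fromarray(grid, mode="RGB").save(path)


def report(out_dir: str | Path, write_grids: bool = True) -> str:
    """Human-readable run summary; missing artifacts are listed as absent."""
    out = Path(out_dir)
    lines = [f"histosynth run summary: {out}"]
    sel = out / "k_selection.json"
    if sel.exists():
        info = json.loads(sel.read_text())
        lines.append(f"consensus k: {info['selected_k']} (winners: {info['winners']})")
    else:
        lines.append("validity selection: not run")
    vcsv = out / "validity_indices.csv"
    if vcsv.exists():
        lines.append("validity indices:\n" + pd.read_csv(vcsv).to_string(index=False))
    scsv = out / "similarity.csv"
    if scsv.exists():
        lines.append("generation quality:\n" + pd.read_csv(scsv).to_string(index=False))
    else:
        lines.append("generation quality: not run")
    fcsv = out / "fidelity.csv"
    if fcsv.exists():
        tab = pd.read_csv(fcsv)
        overall = tab[tab.cluster == -1].accuracy.iloc[0]
        lines.append(f"conditional fidelity (overall): {overall:.3f}")
        lines.append(tab[tab.cluster >= 0].to_string(index=False))
    else:
        lines.append("conditional fidelity: not run")
    if write_grids:
        for name, sub in [("originals", "fixtures/train"), ("generated", "generated")]:
            d = out / sub
            if d.exists():
                try:
                    _image_grid(read_tiles(d), out / f"grid_{name}.png")
                    lines.append(f"wrote grid_{name}.png")
                except IOError:
                    pass
    text = "\n".join(lines)
    (out / "summary.txt").write_text(text)
    return text
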