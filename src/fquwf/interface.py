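"""Shared I/O, configuration, seed fan-out, and the command-line surface.

Images are RGB float arrays in [0, 1] everywhere inside the package; 8-bit
(or 16-bit) integer encodings exist only at the file boundary. A single
global seed fans out to per-component seeds through a stable label-hash
scheme, so partial re-runs of the pipeline reproduce the full run's
behavior component by component.

The ``fquwf`` command exposes the pipeline: ``synth`` (build an unpaired
phantom dataset), ``degrade`` (apply one operator or a JSON chain),
``train`` (one stage or the whole schedule from a YAML config), ``enhance``
(run the trained two-step model on an image, either ordering), and
``evaluate`` (metric report for two image directories). Every run records a
provenance block (config hash, seed, package version).
"""

from __future__ import annotations

import argparse
import hashlib
import json
import sys
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml
from PIL import Image as PILImage

__all__ = [
    "load_image", "save_image", "load_mask", "save_mask",
    "derive_seed", "RunConfig", "run_pipeline", "cli_main", "main",
]

__version__ = "0.1.0"


# -- image I/O ----------------------------------------------------------------

def load_image(path) -> np.ndarray:
    """Read PNG/JPEG/TIFF into an H x W x 3 float array in [0, 1].

    Grayscale files are promoted to three identical channels; 16-bit files
    are scaled by their bit depth.
    """
    path = Path(path)
    try:
        im = PILImage.open(path)
        im.load()
    except (OSError, FileNotFoundError) as exc:
        raise IOError(f"cannot read image {path}: {exc}") from exc
    arr = np.asarray(im)
    if arr.dtype == np.uint8:
        out = arr.astype(np.float64) / 255.0
    elif arr.dtype == np.uint16:
        out = arr.astype(np.float64) / 65535.0
    elif arr.dtype == np.int32:   # PIL mode "I" (32-bit) stores 16-bit TIFFs
        out = arr.astype(np.float64) / 65535.0
    else:
        out = arr.astype(np.float64)
    if out.ndim == 2:
        out = np.repeat(out[..., None], 3, axis=2)
    if out.shape[2] == 4:
        out = out[..., :3]
    return np.clip(out, 0.0, 1.0)


def save_image(img: np.ndarray, path) -> None:
    """Write an H x W x 3 [0, 1] array as 8-bit RGB PNG (or by extension)."""
    img = np.asarray(img, dtype=np.float64)
    u8 = (np.clip(img, 0.0, 1.0) * 255.0).round().astype(np.uint8)
    try:
        PILImage.fromarray(u8, mode="RGB").save(Path(path))
    except OSError as exc:
        raise IOError(f"cannot write image {path}: {exc}") from exc


def load_mask(path) -> np.ndarray:
    """Read a single-channel 0/255 PNG into a boolean H x W array."""
    try:
        im = PILImage.open(Path(path)).convert("L")
    except (OSError, FileNotFoundError) as exc:
        raise IOError(f"cannot read mask {path}: {exc}") from exc
    return np.asarray(im) > 127


def save_mask(mask: np.ndarray, path) -> None:
    u8 = (np.asarray(mask).astype(bool) * 255).astype(np.uint8)
    PILImage.fromarray(u8, mode="L").save(Path(path))


# -- seed fan-out -------------------------------------------------------------

def derive_seed(global_seed: int, label: str) -> int:
    """Stable per-component seed: mix the global seed with a label hash."""
    h = zlib.crc32(label.encode("utf-8"))
    return int((np.uint64(global_seed) * np.uint64(2654435761) ^ np.uint64(h))
               % np.uint64(2 ** 31))


# -- run configuration --------------------------------------------------------

_STAGE_KEYS = ("pretrain", "de", "sr", "ft")


@dataclass
class RunConfig:
    """Whole-pipeline configuration, YAML round-trippable, strict keys."""

    seed: int = 0
    output_root: str = "runs/fquwf"
    phantom: dict = field(default_factory=dict)     # PhantomParams kwargs
    chain: list = field(default_factory=list)       # DegradationSpec dicts
    data: dict = field(default_factory=lambda: {"n_train": 40, "n_eval": 16})
    network: dict = field(default_factory=dict)     # NetConfig kwargs
    weights: dict = field(default_factory=dict)     # LossWeights kwargs
    stages: dict = field(default_factory=dict)      # per-stage StageConfig kwargs
    evaluation: dict = field(default_factory=lambda: {"alpha": 0.05})

    def __post_init__(self):
        unknown = set(self.stages) - set(_STAGE_KEYS)
        if unknown:
            raise ValueError(f"unknown stage keys: {sorted(unknown)}")

    @staticmethod
    def from_yaml(path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        allowed = set(RunConfig.__dataclass_fields__)
        unknown = set(doc) - allowed
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return RunConfig(**doc)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    # typed accessors ---------------------------------------------------
    def phantom_params(self):
        from .phantom import PhantomParams
        p = dict(self.phantom)
        if "background_tint" in p:
            p["background_tint"] = tuple(p["background_tint"])
        return PhantomParams(**p)

    def degradation_chain(self):
        from .degradations import DegradationSpec
        from .phantom import default_uwf_chain
        if not self.chain:
            return default_uwf_chain()
        return [DegradationSpec.from_dict(d) for d in self.chain]

    def net_config(self):
        from .networks import NetConfig
        if not self.network:
            return NetConfig.tiny()
        return NetConfig(**self.network)

    def loss_weights(self):
        from .objectives import LossWeights
        return LossWeights(**self.weights)

    def stage_config(self, stage: str):
        from .training import StageConfig
        kw = dict(self.stages.get(stage.lower(), {}))
        kw.setdefault("seed", derive_seed(self.seed, "stage-" + stage.lower()))
        iterations = kw.pop("iterations", 500 if stage != "FT" else 200)
        return StageConfig.tiny(stage, iterations=iterations, **kw)


def write_provenance(out_root, config: RunConfig | None, seed: int) -> dict:
    block = {
        "config_hash": config.config_hash() if config else None,
        "config": asdict(config) if config else None,
        "seed": int(seed),
        "version": __version__,
    }
    out_root = Path(out_root)
    out_root.mkdir(parents=True, exist_ok=True)
    with open(out_root / "provenance.json", "w") as fh:
        json.dump(block, fh, indent=2)
    return block


# -- whole-pipeline runner -----------------------------------------------------

def run_pipeline(config: RunConfig, stages=("pretrain", "de", "sr", "ft")) -> dict:
    """Synthesize data and run the requested training stages in order.

    Returns a summary with the dataset manifests, the checkpoint directory,
    and the per-stage loss histories. Later stages require the checkpoints
    of earlier ones (a staging error is raised otherwise).
    """
    from .phantom import build_unpaired_dataset
    from .training import (make_pretrain_pairs, pretrain_gde, train_stage_de,
                           train_stage_sr, finetune_macular, load_checkpoint,
                           StagingError)
    from .networks import build_gde, build_gsr, build_discriminator

    root = Path(config.output_root)
    root.mkdir(parents=True, exist_ok=True)
    params = config.phantom_params()
    chain = config.degradation_chain()
    net_cfg = config.net_config()
    weights = config.loss_weights()
    ckpt_dir = root / "ckpt"
    logs_dir = root / "logs"
    logs_dir.mkdir(exist_ok=True)

    train_manifest = build_unpaired_dataset(
        params, int(config.data.get("n_train", 40)),
        root / "data" / "clean", root / "data" / "uwf",
        derive_seed(config.seed, "train-data"), chain=chain)
    eval_manifest = build_unpaired_dataset(
        params, int(config.data.get("n_eval", 16)),
        root / "eval" / "clean", root / "eval" / "uwf",
        derive_seed(config.seed, "eval-data"), chain=chain)

    summary = {"root": str(root), "ckpt_dir": str(ckpt_dir),
               "train_manifest": train_manifest,
               "eval_manifest": eval_manifest, "losses": {}}

    gde = anchor = gsr = dde = dsr = None
    uwf_dir, clean_dir = root / "data" / "uwf", root / "data" / "clean"

    if "pretrain" in stages:
        pairs = make_pretrain_pairs(params, int(config.data.get("n_train", 40)),
                                    chain,
                                    seed=derive_seed(config.seed, "pretrain"))
        cfg = config.stage_config("PRETRAIN")
        gde, anchor = pretrain_gde(pairs, cfg, net_cfg, run_dir=ckpt_dir,
                                   log_path=logs_dir / "pretrain.jsonl")
    if "de" in stages:
        if gde is None:
            arrays, _ = load_checkpoint(ckpt_dir, "PRETRAIN")
            gde = build_gde(net_cfg,
                            seed=config.stage_config("PRETRAIN").seed)
            from .training import _restore_model
            _restore_model(gde, arrays, "gde")
            anchor = {k[len("anchor/"):]: v for k, v in arrays.items()
                      if k.startswith("anchor/")}
        if anchor is None:
            raise StagingError("stage DE requires the pretraining anchor")
        cfg = config.stage_config("DE")
        st = train_stage_de(uwf_dir, clean_dir, gde, anchor, cfg, net_cfg,
                            weights, run_dir=ckpt_dir,
                            log_path=logs_dir / "de.jsonl")
        dde = st.models["dde"]
        summary["losses"]["de"] = [b.to_dict() for b in st.loss_history]
    if "sr" in stages:
        cfg = config.stage_config("SR")
        st = train_stage_sr(uwf_dir, clean_dir, gde, gsr, cfg, net_cfg,
                            weights, run_dir=ckpt_dir,
                            log_path=logs_dir / "sr.jsonl")
        gde, gsr, dsr = st.models["gde"], st.models["gsr"], st.models["dsr"]
        summary["losses"]["sr"] = [b.to_dict() for b in st.loss_history]
    if "ft" in stages:
        cfg = config.stage_config("FT")
        centers = train_manifest["macula_centers"]
        pairing = train_manifest["pairing"]
        uwf_centers = [tuple(np.asarray(centers[pairing[j]]) / 4.0)
                       for j in range(len(pairing))]
        st = finetune_macular(uwf_dir, clean_dir, gde, gsr, dde, dsr, anchor,
                              cfg, net_cfg, weights,
                              macula_centers=[tuple(c) for c in centers],
                              uwf_macula_centers=uwf_centers,
                              run_dir=ckpt_dir,
                              log_path=logs_dir / "ft.jsonl")
        summary["losses"]["ft"] = [b.to_dict() for b in st.loss_history]

    write_provenance(root, config, config.seed)
    return summary


def load_trained_networks(run_root):
    """Rebuild (gde, gsr, net_cfg) from the newest stage checkpoint under
    <run_root>/ckpt, preferring FT > SR; raises a staging error if absent."""
    from .training import load_checkpoint, _restore_model, StagingError
    from .networks import build_gde, build_gsr

    root = Path(run_root)
    prov_path = root / "provenance.json"
    if not prov_path.exists():
        raise StagingError(f"no provenance.json under {root}; train first")
    with open(prov_path) as fh:
        prov = json.load(fh)
    config = RunConfig(**prov["config"])
    net_cfg = config.net_config()
    ckpt_dir = root / "ckpt"
    last_err = None
    for stage in ("FT", "SR"):
        try:
            arrays, _ = load_checkpoint(ckpt_dir, stage)
        except StagingError as exc:
            last_err = exc
            continue
        gde = build_gde(net_cfg, seed=0)
        gsr = build_gsr(net_cfg, seed=0)
        _restore_model(gde, arrays, "gde")
        _restore_model(gsr, arrays, "gsr")
        return gde, gsr, net_cfg
    raise StagingError(f"no SR or FT checkpoint under {ckpt_dir}: {last_err}")


# -- command-line interface ----------------------------------------------------

def _build_parser() -> argparse.ArgumentParser:
    ap = argparse.ArgumentParser(
        prog="fquwf",
        description="Unpaired enhancement + x4 super-resolution for "
                    "ultra-widefield retinal images")
    sub = ap.add_subparsers(dest="command", required=True)

    p = sub.add_parser("synth", help="build an unpaired phantom dataset")
    p.add_argument("--n", type=int, required=True)
    p.add_argument("--seed", type=int, default=0)
    p.add_argument("--out", required=True)
    p.add_argument("--size", type=int, default=96)
    p.add_argument("--n-vessels", type=int, default=7)
    p.add_argument("--n-drusen", type=int, default=5)
    p.add_argument("--noise-sd", type=float, default=0.01)

    p = sub.add_parser("degrade", help="apply a degradation operator or chain")
    p.add_argument("input")
    p.add_argument("output")
    p.add_argument("--kind", choices=["gaussian_blur", "illumination",
                                      "jpeg", "bicubic"])
    p.add_argument("--sigma", type=float)
    p.add_argument("--gamma", type=float)
    p.add_argument("--rate", type=float)
    p.add_argument("--scale", type=float)
    p.add_argument("--chain", help="JSON file with a list of operator specs")

    p = sub.add_parser("train", help="run training stages from a YAML config")
    p.add_argument("--config", required=True)
    p.add_argument("--stage", default="all",
                   choices=["pretrain", "de", "sr", "ft", "all"])

    p = sub.add_parser("enhance", help="enhance + super-resolve one image")
    p.add_argument("input")
    p.add_argument("output")
    p.add_argument("--ckpt", required=True, help="training output root")
    p.add_argument("--order", default="de_sr", choices=["de_sr", "sr_de"])
    p.add_argument("--intermediate", help="also save the interim result here")

    p = sub.add_parser("evaluate", help="metric report for two directories")
    p.add_argument("--pred-dir", required=True)
    p.add_argument("--ref-dir", required=True)
    p.add_argument("--masks-pred")
    p.add_argument("--masks-gt")
    p.add_argument("--out", required=True)
    p.add_argument("--alpha", type=float, default=0.05)
    return ap


def cli_main(argv=None) -> int:
    from .training import StagingError

    parser = _build_parser()
    try:
        args = parser.parse_args(argv)
    except SystemExit as exc:
        return int(exc.code) if exc.code else 0

    try:
        if args.command == "synth":
            from .phantom import PhantomParams, build_unpaired_dataset
            params = PhantomParams(size=args.size, n_vessels=args.n_vessels,
                                   n_drusen=args.n_drusen,
                                   noise_sd=args.noise_sd)
            out = Path(args.out)
            build_unpaired_dataset(params, args.n, out / "clean", out / "uwf",
                                   args.seed)
            write_provenance(out, None, args.seed)
            return 0

        if args.command == "degrade":
            from .degradations import DegradationSpec, apply_chain
            img = load_image(args.input)
            if args.chain:
                with open(args.chain) as fh:
                    chain = [DegradationSpec.from_dict(d)
                             for d in json.load(fh)]
            elif args.kind:
                chain = [DegradationSpec(args.kind, sigma=args.sigma,
                                         gamma=args.gamma, rate=args.rate,
                                         scale=args.scale)]
            else:
                parser.error("degrade requires --kind or --chain")
            save_image(apply_chain(img, chain), args.output)
            return 0

        if args.command == "train":
            config = RunConfig.from_yaml(args.config)
            stages = (("pretrain", "de", "sr", "ft")
                      if args.stage == "all" else (args.stage,))
            run_pipeline(config, stages=stages)
            return 0

        if args.command == "enhance":
            from .training import enhance
            gde, gsr, _ = load_trained_networks(args.ckpt)
            img = load_image(args.input)
            out, inter = enhance(img, gde, gsr, order=args.order,
                                 return_intermediate=True)
            save_image(out, args.output)
            if args.intermediate:
                save_image(inter, args.intermediate)
            sidecar = {"order": args.order, "ckpt": str(args.ckpt),
                       "version": __version__}
            with open(str(args.output) + ".provenance.json", "w") as fh:
                json.dump(sidecar, fh)
            return 0

        if args.command == "evaluate":
            from .evaluation import build_report
            report = build_report(args.pred_dir, args.ref_dir,
                                  masks_pred=args.masks_pred,
                                  masks_gt=args.masks_gt, alpha=args.alpha)
            report["provenance"] = {"version": __version__}
            with open(args.out, "w") as fh:
                json.dump(report, fh, indent=2)
            return 0
    except (StagingError, IOError, ValueError) as exc:
        print(f"fquwf: error: {exc}", file=sys.stderr)
        return 1
    return 2


def main() -> None:
    sys.exit(cli_main())
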