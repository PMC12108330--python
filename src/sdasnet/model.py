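"""Full network assembly, parameter accounting and checkpoint I/O.

Data flow: wavelet front end (spatial /2, optionally /4 with the strided
fusion conv) -> four star-block encoder stages with doubling widths ->
bottleneck -> dual cross-attention refinement of the four skips -> four
EMCA decoder stages -> bilinear upsampling back to the input resolution ->
1x1 convolution to per-class logits.

The default configuration targets 512x512 RGB input with a two-class head;
its base width is calibrated so the trainable parameter count sits at the
1.26e7 scale of the published architecture (see scripts/calibrate_width.py).
"""

from __future__ import annotations

import io
import json
from dataclasses import asdict, dataclass, field

import numpy as np

from . import nn
from .dca import DCA, DCAConfig
from .dwt_module import DWTFrontEnd, DWTModuleConfig
from .emca import Decoder, EMCAConfig
from .star import Encoder, EncoderConfig, StarBlockConfig

#: Default base width, calibrated against the published model complexity
#: (1.26e7 trainable parameters for the 512x512 configuration).
DEFAULT_BASE_WIDTH = 35


@dataclass
class ModelConfig:
    base_width: int = DEFAULT_BASE_WIDTH
    input_size: tuple = (512, 512)
    num_classes: int = 2
    dwt: DWTModuleConfig = None
    star: StarBlockConfig = None
    emca: EMCAConfig = None
    dca: DCAConfig = None

    def __post_init__(self):
        if self.num_classes < 2:
            raise ValueError("num_classes must be >= 2")
        if self.dwt is None:
            self.dwt = DWTModuleConfig(out_channels=self.base_width,
                                       mid_channels=max(self.base_width // 2, 1))
        if self.star is None:
            self.star = StarBlockConfig(channels=self.base_width)
        if self.emca is None:
            self.emca = EMCAConfig()
        h, w = self.input_size
        fs = self.dwt.final_stride
        unit = 2 * fs * 16
        if h % unit or w % unit:
            raise ValueError(
                f"input_size {self.input_size} must be divisible by {unit} "
                f"(wavelet front end x{2 * fs}, four pooling stages x16)")
        deepest = min(h, w) // (2 * fs) // 8
        if self.dca is None:
            self.dca = DCAConfig(token_grid=deepest)
        g = self.dca.token_grid
        if deepest % g:
            raise ValueError(
                f"token grid {g} must divide the deepest skip size {deepest}")

    @property
    def stage_widths(self) -> list[int]:
        return [self.base_width * 2 ** i for i in range(4)]


class SDASNet(nn.Module):
    def __init__(self, config: ModelConfig, rng: np.random.Generator,
                 dtype=np.float32):
        super().__init__()
        self.config = config
        enc_cfg = EncoderConfig(base_width=config.base_width, star=config.star)
        self.front = DWTFrontEnd(config.dwt, rng, dtype)
        self.encoder = Encoder(config.dwt.out_channels, enc_cfg, rng, dtype)
        self.dca = DCA(config.stage_widths, config.dca, rng, dtype)
        self.decoder = Decoder(self.encoder.bottleneck_width,
                               config.stage_widths, config.emca, rng, dtype)
        # restore the front end's x(2*final_stride) reduction before the head
        self.n_upsamples = 1 + (config.dwt.final_stride == 2)
        self.head = nn.Conv2d(config.base_width, config.num_classes, 1, rng,
                              dtype=dtype)

    def forward(self, batch) -> nn.Tensor:
        data = batch.data if isinstance(batch, nn.Tensor) else np.asarray(batch)
        if data.ndim != 4:
            raise ValueError(f"expected (N, C, H, W) batch, got shape {data.shape}")
        h, w = self.config.input_size
        if data.shape[2] != h or data.shape[3] != w:
            raise ValueError(
                f"batch spatial size {data.shape[2:]} != configured {(h, w)}")
        fo = self.front(data)
        skips, bottleneck = self.encoder(fo)
        refined = self.dca(skips)
        y = self.decoder(bottleneck, refined)
        for _ in range(self.n_upsamples):
            y = nn.upsample_bilinear(y, (y.shape[2] * 2, y.shape[3] * 2))
        return self.head(y)

    def predict_mask(self, batch) -> np.ndarray:
        """Argmax segmentation: (N, H, W) uint8 in {0, 255}."""
        logits = self.forward(batch)
        return (logits.data.argmax(axis=1) * 255).astype(np.uint8)


def build_model(config: ModelConfig | None = None, seed: int = 0,
                dtype=np.float32) -> SDASNet:
    """Construct the network with reproducible, seeded weight init."""
    if config is None:
        config = ModelConfig()
    rng = np.random.default_rng(seed)
    return SDASNet(config, rng, dtype)


def count_parameters(model: nn.Module) -> int:
    return model.count_parameters()


def summarize(model: SDASNet) -> str:
    """Layer table: parameter count per top-level block plus the total."""
    groups: dict[str, int] = {}
    for name, p in model.named_parameters():
        top = name.split(".", 1)[0]
        groups[top] = groups.get(top, 0) + p.data.size
    lines = [f"{'block':<12}{'parameters':>12}"]
    for top, n in groups.items():
        lines.append(f"{top:<12}{n:>12,}")
    total = sum(groups.values())
    lines.append(f"{'total':<12}{total:>12,}")
    return "\n".join(lines)


# -- checkpointing ------------------------------------------------------------

def _config_to_dict(config: ModelConfig) -> dict:
    return asdict(config)


def _config_from_dict(d: dict) -> ModelConfig:
    return ModelConfig(
        base_width=d["base_width"],
        input_size=tuple(d["input_size"]),
        num_classes=d["num_classes"],
        dwt=DWTModuleConfig(**d["dwt"]),
        star=StarBlockConfig(**d["star"]),
        emca=EMCAConfig(**d["emca"]),
        dca=DCAConfig(**d["dca"]),
    )


def save_checkpoint(model: SDASNet, path) -> None:
    """Single-file weight map keyed by module path, with the config embedded."""
    state = {f"param/{k}": v for k, v in model.state_dict().items()}
    state["config_json"] = np.frombuffer(
        json.dumps(_config_to_dict(model.config)).encode(), dtype=np.uint8)
    np.savez(path, **state)


def load_checkpoint(path) -> SDASNet:
    with np.load(path) as archive:
        config = _config_from_dict(
            json.loads(archive["config_json"].tobytes().decode()))
        model = build_model(config, seed=0)
        model.load_state_dict({k[len("param/"):]: archive[k]
                               for k in archive.files if k.startswith("param/")})
    return model
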