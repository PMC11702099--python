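"""Model-complexity accounting: trainable-parameter counts and analytic
forward-pass cost.

Two independent counters are provided: closed-form per-layer arithmetic
derived from the configuration (conv: Cin·Cout·k² + Cout bias; depthwise:
C·k² + C; linear: in·out + out; affine instance norm: 2C), and direct
enumeration of every trainable scalar in instantiated networks with shared
storage counted once.  Forward cost sums per-layer multiply–accumulate
counts (conv: Cin·Cout·k²·Hout·Wout; depthwise: C·k²·Hout·Wout; transposed
conv: Cin·Cout·k²·Hout·Wout; linear: in·out) over one full forward pass —
classifier, both generator paths and all three discriminator scales on one
pair.  Both FLOP conventions (1 MAC = 1 FLOP, 1 MAC = 2 FLOPs) are
reported; the calibrated default is MAC = 1 FLOP.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from .classifier import ClassifierConfig, Her2Classifier
from .discriminator import DiscriminatorConfig, MultiScaleDiscriminator
from .generator import GeneratorConfig, DualScaleGenerator
from .nn import Module

MAC1 = "macs=1flop"
MAC2 = "macs=2flops"


@dataclass
class ComplexityReport:
    params_total: int
    params_by_component: dict
    gmacs_forward: float
    gflops_forward: float      # under `convention`
    gflops_total: float        # forward + backward (2x forward)
    convention: str = MAC1
    gmacs_by_component: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "params_total": self.params_total,
            "params_total_millions": round(self.params_total / 1e6, 4),
            "params_by_component": self.params_by_component,
            "gmacs_forward": self.gmacs_forward,
            "gmacs_by_component": self.gmacs_by_component,
            "gflops_forward_mac1": self.gmacs_forward,
            "gflops_forward_mac2": 2.0 * self.gmacs_forward,
            "gflops_forward": self.gflops_forward,
            "gflops_total": self.gflops_total,
            "convention": self.convention,
        }

    def to_json(self) -> str:
        return json.dumps(self.as_dict(), indent=1)


# --------------------------------------------------------- closed-form params

def _conv_p(cin, cout, k):
    return cin * cout * k * k + cout


def _dw_p(c, k=3):
    return c * k * k + c


def _lin_p(cin, cout):
    return cin * cout + cout


def _in_p(c, affine=True):
    return 2 * c if affine else 0


def _conv_in_p(cin, cout, k):
    return _conv_p(cin, cout, k) + _in_p(cout)


def _ir_p(c, e):
    ce = c * e
    return (_conv_p(c, ce, 1) + _in_p(ce) + _dw_p(ce) + _in_p(ce)
            + _conv_p(ce, c, 1) + _in_p(c))


def _adain_p(ed, hidden, c):
    return _lin_p(ed, hidden) + _lin_p(hidden, 2 * c)


def generator_param_count(g: GeneratorConfig) -> int:
    w, e, ed, ah = g.base_width, g.ir_expansion, g.label_embed_dim, g.adain_hidden
    t32, t16 = g.tap_channels
    total = 0
    total += _conv_in_p(3, w, 7)            # shared stem
    total += _conv_in_p(w, 2 * w, 3)        # shared down1
    total += _conv_in_p(2 * w, 4 * w, 3)    # down2
    total += _conv_in_p(4 * w, 8 * w, 3)    # down3
    total += _conv_in_p(2 * w, 4 * w, 3)    # low_down2
    total += _conv_p(8 * w + 4 * w + t32 + t16, 8 * w, 1) + _in_p(8 * w)  # fuse
    total += 4 * ed                          # level embedding
    total += g.full_ir_blocks * _ir_p(8 * w, e)
    total += g.low_ir_blocks * _ir_p(4 * w, e)
    for cin, cout in ((8 * w, 4 * w), (4 * w, 2 * w), (2 * w, w)):  # full decoder
        total += _conv_p(cin, cout, 3) + _adain_p(ed, ah, cout)
    total += _conv_p(w, 3, 7)
    for cin, cout in ((4 * w, 2 * w), (2 * w, w)):                  # low decoder
        total += _conv_p(cin, cout, 3) + _adain_p(ed, ah, cout)
    total += _conv_p(w, 3, 7)
    return total


def _se_p(cexp):
    h = max(4, cexp // 4)
    return _lin_p(cexp, h) + _lin_p(h, cexp)


def classifier_param_count(c: ClassifierConfig) -> int:
    # batch-norm affine terms count 2C like any affine norm; running
    # statistics are buffers, not trainable parameters
    total = _conv_p(3, c.stem, 3) + _in_p(c.stem)
    cin = c.stem
    for b in c.blocks:
        if b.exp != cin:
            total += _conv_p(cin, b.exp, 1) + _in_p(b.exp)
        total += _dw_p(b.exp) + _in_p(b.exp)
        if b.se:
            total += _se_p(b.exp)
        total += _conv_p(b.exp, b.out, 1) + _in_p(b.out)
        cin = b.out
    total += _conv_p(cin, c.head_conv, 1) + _in_p(c.head_conv)
    total += _lin_p(c.head_conv, c.head_hidden)
    total += _lin_p(c.head_hidden, c.n_classes)
    return total


def discriminator_param_count(d: DiscriminatorConfig) -> int:
    per_scale = 0
    cin = 6
    for wd in d.widths:
        per_scale += _conv_p(cin, wd, 4)
        cin = wd
    per_scale += _conv_p(cin, 1, 4)   # instance norms carry no affine params
    return d.n_scales * per_scale


# ----------------------------------------------------------- enumeration

def count_parameters(nets: dict[str, Module]) -> dict:
    """Enumerate trainable scalars per component; shared storage within a
    component (or across components) is counted once, on first sight."""
    seen: set[int] = set()
    by_component = {}
    for name, net in nets.items():
        n = 0
        for p in net.parameters():
            if id(p) in seen:
                continue
            seen.add(id(p))
            n += p.data.size
        by_component[name] = int(n)
    by_component["total"] = int(sum(v for k, v in by_component.items() if k != "total"))
    return by_component


# --------------------------------------------------------------- MAC counts

def _conv_m(cin, cout, k, out_side):
    return cin * cout * k * k * out_side * out_side


def _dw_m(c, k, out_side):
    return c * k * k * out_side * out_side


def generator_macs(g: GeneratorConfig, side: int = 256) -> int:
    w, e, ed, ah = g.base_width, g.ir_expansion, g.label_embed_dim, g.adain_hidden
    t32, t16 = g.tap_channels
    m = 0
    # full path
    m += _conv_m(3, w, 7, side)
    m += _conv_m(w, 2 * w, 3, side // 2)
    m += _conv_m(2 * w, 4 * w, 3, side // 4)
    m += _conv_m(4 * w, 8 * w, 3, side // 8)
    s8 = side // 8
    m += _conv_m(12 * w + t32 + t16, 8 * w, 1, s8)
    for _ in range(g.full_ir_blocks):
        ce = 8 * w * e
        m += _conv_m(8 * w, ce, 1, s8) + _dw_m(ce, 3, s8) + _conv_m(ce, 8 * w, 1, s8)
    for cin, cout, out_side in ((8 * w, 4 * w, side // 4), (4 * w, 2 * w, side // 2),
                                (2 * w, w, side)):
        m += _conv_m(cin, cout, 3, out_side)        # transposed conv, output convention
        m += ed * ah + ah * 2 * cout                # AdaIN MLP
    m += _conv_m(w, 3, 7, side)
    # low path (input side/4)
    s = side // 4
    m += _conv_m(3, w, 7, s)
    m += _conv_m(w, 2 * w, 3, s // 2)
    m += _conv_m(2 * w, 4 * w, 3, s // 4)
    ce = 4 * w * e
    for _ in range(g.low_ir_blocks):
        m += _conv_m(4 * w, ce, 1, s // 4) + _dw_m(ce, 3, s // 4) + _conv_m(ce, 4 * w, 1, s // 4)
    for cin, cout, out_side in ((4 * w, 2 * w, s // 2), (2 * w, w, s)):
        m += _conv_m(cin, cout, 3, out_side)
        m += ed * ah + ah * 2 * cout
    m += _conv_m(w, 3, 7, s)
    return m


def classifier_macs(c: ClassifierConfig, side: int = 256) -> int:
    m = _conv_m(3, c.stem, 3, side // 2)
    cur = side // 2
    cin = c.stem
    for b in c.blocks:
        out_side = cur // b.stride
        if b.exp != cin:
            m += _conv_m(cin, b.exp, 1, cur)
        m += _dw_m(b.exp, 3, out_side)
        if b.se:
            h = max(4, b.exp // 4)
            m += b.exp * h + h * b.exp
        m += _conv_m(b.exp, b.out, 1, out_side)
        cin, cur = b.out, out_side
    m += _conv_m(cin, c.head_conv, 1, cur)
    m += c.head_conv * c.head_hidden
    m += c.head_hidden * c.n_classes
    return m


def discriminator_macs(d: DiscriminatorConfig, side: int = 256) -> int:
    m = 0
    s = side
    for _ in range(d.n_scales):
        cin, cur = 6, s
        for wd in d.widths:
            cur = cur // 2
            m += _conv_m(cin, wd, 4, cur)
            cin = wd
        m += _conv_m(cin, 1, 4, cur - 1)   # final stride-1 4×4, pad 1: side-1
        s = s // 2
    return m


# ------------------------------------------------------------------- report

def complexity_report(gcfg: GeneratorConfig, ccfg: ClassifierConfig,
                      dcfg: DiscriminatorConfig, side: int = 256,
                      convention: str = MAC1,
                      verify_with_instances: bool = True) -> ComplexityReport:
    params = {
        "generator": generator_param_count(gcfg),
        "classifier": classifier_param_count(ccfg),
        "discriminators": discriminator_param_count(dcfg),
    }
    params["total"] = sum(params.values())
    if verify_with_instances:
        enumerated = count_parameters({
            "generator": DualScaleGenerator(gcfg),
            "classifier": Her2Classifier(ccfg),
            "discriminators": MultiScaleDiscriminator(dcfg),
        })
        for key in ("generator", "classifier", "discriminators", "total"):
            if enumerated[key] != params[key]:
                raise AssertionError(
                    f"parameter counters disagree for {key}: closed-form "
                    f"{params[key]} vs enumerated {enumerated[key]}"
                )
    macs = {
        "generator": generator_macs(gcfg, side),
        "classifier": classifier_macs(ccfg, side),
        "discriminators": discriminator_macs(dcfg, side),
    }
    gmacs = sum(macs.values()) / 1e9
    factor = 1.0 if convention == MAC1 else 2.0
    return ComplexityReport(
        params_total=params["total"],
        params_by_component={k: v for k, v in params.items() if k != "total"},
        gmacs_forward=round(gmacs, 4),
        gflops_forward=round(gmacs * factor, 4),
        gflops_total=round(2.0 * gmacs * factor, 4),
        convention=convention,
        gmacs_by_component={k: round(v / 1e9, 4) for k, v in macs.items()},
    )
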