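"""Realize a :class:`~mammodense.arch.NetworkSpec` as an executable network.

Each block of the spec is compiled to a small object holding its
parameters; the network walks the encoder, bottleneck and decoder in
spec order, maintaining the skip stack exactly as the spec's dataflow
prescribes.  Weight initialization is He-uniform for convolutions and
identity for batch norm, seeded for reproducibility.
"""

from __future__ import annotations

import numpy as np

from ..arch import NetworkSpec, downsample_factor, effective_kernel_size
from . import tape
from .tape import Tensor


def _he_uniform(rng, shape):
    fan_in = int(np.prod(shape[1:]))
    bound = np.sqrt(6.0 / fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(np.float32)


class ConvOp:
    """3x3/1x1 (possibly strided or atrous) convolution with bias."""

    def __init__(self, rng, in_ch, out_ch, kernel, stride=1, dilation=1):
        self.kernel = kernel
        self.stride = stride
        self.dilation = dilation
        self.w = Tensor(_he_uniform(rng, (out_ch, in_ch, kernel, kernel)),
                        requires_grad=True)
        self.b = Tensor(np.zeros(out_ch, dtype=np.float32), requires_grad=True)

    def __call__(self, x):
        eff = effective_kernel_size(self.kernel, self.dilation) \
            if self.kernel % 2 == 1 else self.kernel
        if self.stride == 1:
            pad = (eff - 1) // 2
        else:
            # stride-2 "same": halve the side exactly (even sides only)
            side = x.data.shape[2]
            if side % 2 != 0:
                raise ValueError(
                    f"stride-2 convolution on odd side {side} is ambiguous "
                    "under same padding")
            pad = (eff - 1) // 2
        return tape.conv2d(x, self.w, self.b, stride=self.stride,
                           dilation=self.dilation, padding=pad)

    def params(self):
        return [("w", self.w), ("b", self.b)]


class TransposedConvOp:
    def __init__(self, rng, in_ch, out_ch, kernel=3, stride=2):
        self.stride = stride
        self.w = Tensor(_he_uniform(rng, (out_ch, in_ch, kernel, kernel)),
                        requires_grad=True)
        self.b = Tensor(np.zeros(out_ch, dtype=np.float32), requires_grad=True)

    def __call__(self, x):
        return tape.conv_transpose2d(x, self.w, self.b, stride=self.stride)

    def params(self):
        return [("w", self.w), ("b", self.b)]


class BatchNormOp:
    def __init__(self, channels, momentum=0.1, eps=1e-5):
        self.gamma = Tensor(np.ones(channels, dtype=np.float32),
                            requires_grad=True)
        self.beta = Tensor(np.zeros(channels, dtype=np.float32),
                           requires_grad=True)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x, training):
        return tape.batch_norm(x, self.gamma, self.beta, self.running_mean,
                               self.running_var, momentum=self.momentum,
                               eps=self.eps, training=training)

    def params(self):
        return [("gamma", self.gamma), ("beta", self.beta)]

    def buffers(self):
        return [("running_mean", self.running_mean),
                ("running_var", self.running_var)]


class DenseBlockOp:
    """BN -> ReLU -> 3x3 conv -> dropout, densely connected."""

    def __init__(self, rng, in_ch, n_layers, growth, dropout):
        self.dropout = dropout
        self.bns = []
        self.convs = []
        for i in range(n_layers):
            c = in_ch + i * growth
            self.bns.append(BatchNormOp(c))
            self.convs.append(ConvOp(rng, c, growth, kernel=3))

    def __call__(self, x, training, drop_rng):
        cat = x
        feats = []
        for bn, conv in zip(self.bns, self.convs):
            h = bn(cat, training)
            h = tape.relu(h)
            h = conv(h)
            h = tape.dropout(h, self.dropout, drop_rng, training)
            feats.append(h)
            cat = tape.concat([cat, h])
        return tape.concat(feats) if len(feats) > 1 else feats[0]

    def params(self):
        out = []
        for i, (bn, conv) in enumerate(zip(self.bns, self.convs)):
            out += [(f"l{i}.bn.{n}", p) for n, p in bn.params()]
            out += [(f"l{i}.conv.{n}", p) for n, p in conv.params()]
        return out

    def buffers(self):
        return [(f"l{i}.bn.{n}", b) for i, bn in enumerate(self.bns)
                for n, b in bn.buffers()]


class TransitionDownOp:
    def __init__(self, rng, channels):
        self.conv1 = ConvOp(rng, channels, channels, kernel=1)
        self.conv2 = ConvOp(rng, channels, channels, kernel=3, stride=2)

    def __call__(self, x, training, drop_rng):
        return self.conv2(self.conv1(x))

    def params(self):
        return ([(f"conv1.{n}", p) for n, p in self.conv1.params()]
                + [(f"conv2.{n}", p) for n, p in self.conv2.params()])

    def buffers(self):
        return []


class ASPPOp:
    """Parallel 1x1 + atrous 3x3 branches, concat with input, 1x1 fusion."""

    def __init__(self, rng, in_ch, branch_ch, rates, out_ch):
        self.branches = [ConvOp(rng, in_ch, branch_ch, kernel=1)]
        for r in rates:
            self.branches.append(
                ConvOp(rng, in_ch, branch_ch, kernel=3, dilation=r))
        concat_ch = in_ch + branch_ch * (1 + len(rates))
        self.fusion = ConvOp(rng, concat_ch, out_ch, kernel=1)

    def __call__(self, x, training, drop_rng):
        outs = [x] + [br(x) for br in self.branches]
        return self.fusion(tape.concat(outs))

    def params(self):
        out = []
        for i, br in enumerate(self.branches):
            out += [(f"branch{i}.{n}", p) for n, p in br.params()]
        out += [(f"fusion.{n}", p) for n, p in self.fusion.params()]
        return out

    def buffers(self):
        return []


class ExecutableNetwork:
    """Forward/backward-capable realization of a NetworkSpec."""

    def __init__(self, spec: NetworkSpec, seed: int = 0):
        self.spec = spec
        self.seed = seed
        rng = np.random.default_rng(seed)
        self._drop_rng = np.random.default_rng(
            np.random.SeedSequence(seed).spawn(1)[0])
        self._ops = []
        for b in spec.blocks:
            if b.name == "initial_conv":
                op = ConvOp(rng, b.attrs["in_channels"],
                            b.attrs["out_channels"], kernel=3)
            elif b.name == "dense_block":
                op = DenseBlockOp(rng, b.attrs["in_channels"],
                                  b.attrs["n_layers"], b.attrs["growth"],
                                  b.attrs["dropout"])
            elif b.name == "transition_down":
                op = TransitionDownOp(rng, b.attrs["in_channels"])
            elif b.name == "transition_up":
                op = TransposedConvOp(rng, b.attrs["in_channels"],
                                      b.attrs["out_channels"])
            elif b.name == "aspp":
                op = ASPPOp(rng, b.attrs["in_channels"],
                            b.attrs["branch_channels"], b.attrs["rates"],
                            b.attrs["out_channels"])
            elif b.name == "classifier":
                op = ConvOp(rng, b.attrs["in_channels"],
                            b.attrs["out_channels"], kernel=1)
            else:
                raise ValueError(f"unknown block {b.name!r}")
            self._ops.append(op)

    # -- execution ----------------------------------------------------------

    def forward(self, x: Tensor, training: bool = False) -> Tensor:
        """Map a (1, 1, H, W) input to (1, n_classes, H, W) logits."""
        side = x.data.shape[2]
        factor = downsample_factor(self.spec)
        if side % factor != 0 or x.data.shape[3] % factor != 0:
            raise ValueError(
                f"input sides {x.data.shape[2:]} must be divisible by the "
                f"downsample factor {factor}")
        cur = x
        skips = []
        drop_rng = self._drop_rng
        for b, op in zip(self.spec.blocks, self._ops):
            role = b.attrs.get("role")
            if b.name == "initial_conv":
                cur = op(cur)
            elif b.name == "dense_block" and role == "encoder":
                new = op(cur, training, drop_rng)
                cur = tape.concat([cur, new])
                skips.append(cur)
            elif b.name == "transition_down":
                cur = op(cur, training, drop_rng)
            elif b.name in ("aspp", "dense_block") and role == "bottleneck":
                cur = op(cur, training, drop_rng)
            elif b.name == "transition_up":
                cur = op(cur)
                cur = tape.concat([cur, skips.pop()])
            elif b.name == "dense_block" and role == "decoder":
                new = op(cur, training, drop_rng)
                cur = tape.concat([cur, new]) if b.attrs.get("final_concat") \
                    else new
            elif b.name == "classifier":
                cur = op(cur)
            else:  # pragma: no cover
                raise AssertionError(f"unhandled block {b.name}")
        return cur

    def __call__(self, image: np.ndarray, training: bool = False) -> np.ndarray:
        """Forward a 2-D image; returns (H, W, n_classes) probabilities."""
        x = Tensor(np.asarray(image, dtype=np.float32)[None, None])
        if training:
            logits = self.forward(x, training=True)
        else:
            with tape.no_grad():
                logits = self.forward(x, training=False)
        probs = tape.softmax_channels(logits.data)
        return np.ascontiguousarray(probs[0].transpose(1, 2, 0))

    # -- parameter access ---------------------------------------------------

    def named_parameters(self):
        for i, op in enumerate(self._ops):
            for n, p in op.params():
                yield f"b{i}.{n}", p

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def named_buffers(self):
        for i, op in enumerate(self._ops):
            if hasattr(op, "buffers"):
                for n, b in op.buffers():
                    yield f"b{i}.{n}", b

    def state_dict(self) -> dict[str, np.ndarray]:
        d = {n: p.data.copy() for n, p in self.named_parameters()}
        d.update({f"buf.{n}": b.copy() for n, b in self.named_buffers()})
        return d

    def load_state_dict(self, d: dict[str, np.ndarray]) -> None:
        for n, p in self.named_parameters():
            p.data = np.asarray(d[n], dtype=np.float32).reshape(p.data.shape)
        for n, b in self.named_buffers():
            b[...] = np.asarray(d[f"buf.{n}"], dtype=np.float32)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None


def realize(spec: NetworkSpec, seed: int = 0) -> ExecutableNetwork:
    """Instantiate a spec with seeded weights on the numpy backend."""
    return ExecutableNetwork(spec, seed=seed)


class Adam:
    """Adam optimizer with the standard default betas (0.9, 0.999)."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
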