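"""Mean-Teacher semi-supervised curation of MRI slices into US and NS classes.

Not every slice of a series is equally useful for training a segmentation
network: slices with a clear tumor boundary ("useful slices", US) are easier
to learn from than blurred or nearly tumor-free ones ("normal/difficult
slices", NS).  A small residual classifier (ResNet-7: six residual blocks plus
one fully connected head, 3x3 max pooling between blocks) is trained in a
Mean-Teacher arrangement: the student sees a 70% labeled split (supervised
cross-entropy, Eq. below) and a 30% unlabeled split, on which its predictions
are pulled toward those of a teacher model by a symmetrized
Kullback-Leibler consistency loss

    l2 = 1/2 KL(P_s2 || P_t2) + 1/2 KL(P_t2 || P_s2),

while the teacher tracks the student by an exponential moving average
theta_t' = alpha * theta_t + (1 - alpha) * theta_s' of the parameters.
After training, the teacher splits a slice set at P(US) >= threshold and
orders US slices before NS so a downstream network can learn simple samples
first.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from . import nn
from .nn import Tensor

__all__ = [
    "ResNet7Config",
    "ResNet7",
    "TeacherStudentState",
    "CurationResult",
    "ce_loss",
    "kl_divergence",
    "js_consistency_loss",
    "ema_update",
    "train_curation",
    "split_slices",
    "slices_to_array",
]

EPS = 1e-7


@dataclass
class ResNet7Config:
    """Six residual blocks + one FC head; widths are a free knob (the source
    architecture fixes only the block count)."""

    channels: tuple = (16, 32, 32, 64, 64, 128)
    num_classes: int = 2
    input_size: int = 64  # slices are resampled to input_size x input_size

    def validate(self) -> None:
        if len(self.channels) != 6:
            raise ValueError("ResNet-7 uses exactly 6 residual blocks")


class _ResidualBlock(nn.Module):
    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        self.conv1 = nn.Conv2d(cin, cout, 3, rng)
        self.bn1 = nn.BatchNorm2d(cout)
        self.conv2 = nn.Conv2d(cout, cout, 3, rng)
        self.bn2 = nn.BatchNorm2d(cout)
        self.proj = nn.Conv2d(cin, cout, 1, rng) if cin != cout else None

    def __call__(self, x: Tensor) -> Tensor:
        h = self.bn1(self.conv1(x)).relu()
        h = self.bn2(self.conv2(h))
        skip = self.proj(x) if self.proj is not None else x
        return (h + skip).relu()


class ResNet7(nn.Module):
    """6 residual blocks with inter-block 3x3/stride-2 max pooling, then a
    global average pool and a fully connected softmax head."""

    def __init__(self, config: ResNet7Config, seed: int):
        config.validate()
        rng = np.random.default_rng(seed)
        self.config = config
        chans = config.channels
        self.blocks = [
            _ResidualBlock(cin, cout, rng)
            for cin, cout in zip((1,) + tuple(chans[:-1]), chans)
        ]
        self.fc = nn.Linear(chans[-1], config.num_classes, rng)

    def logits(self, x: Tensor) -> Tensor:
        h = x
        for i, block in enumerate(self.blocks):
            h = block(h)
            if i < len(self.blocks) - 1 and h.data.shape[-1] > 1:
                h = nn.maxpool2d_3s2(h)
        h = h.mean(axis=(2, 3))  # global average pool
        return self.fc(h)

    def __call__(self, x: Tensor) -> Tensor:
        """(N, 1, H, W) -> (N, num_classes) softmax probabilities."""
        return self.logits(x).softmax(axis=1)


@dataclass
class TeacherStudentState:
    student: ResNet7
    teacher: ResNet7
    ema_alpha: float = 0.99
    trained: bool = False
    history: dict = field(default_factory=dict)

    @property
    def theta_s(self) -> list:
        return [p.data for p in self.student.parameters()]

    @property
    def theta_t(self) -> list:
        return [p.data for p in self.teacher.parameters()]


@dataclass
class CurationResult:
    assignment: list  # per-slice "US"/"NS"
    p_us: np.ndarray
    order: np.ndarray  # slice indices, US first
    us_fraction: float
    ns_fraction: float


# -- loss primitives (numpy; the trainers use Tensor twins below) ------------

def ce_loss(p_s1: np.ndarray, y1: np.ndarray) -> float:
    """Binary cross-entropy of P(US) against 0/1 labels, natural log."""
    p = np.clip(np.asarray(p_s1, dtype=float), EPS, 1.0 - EPS)
    y = np.asarray(y1, dtype=float)
    if p.shape != y.shape:
        raise ValueError("probability/label length mismatch")
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def kl_divergence(q: np.ndarray, p: np.ndarray) -> float:
    """KL(Q || P) in this package's convention: sum_x p(x) log(p(x)/q(x))."""
    q = np.asarray(q, dtype=float)
    p = np.asarray(p, dtype=float)
    if (q < 0).any() or (p < 0).any():
        raise ValueError("distributions must be non-negative")
    qc = np.clip(q, EPS, 1.0)
    pc = np.clip(p, EPS, 1.0)
    return float(np.sum(pc * np.log(pc / qc), axis=-1).mean())


def js_consistency_loss(p_s2: np.ndarray, p_t2: np.ndarray) -> float:
    """Symmetrized KL, 1/2 KL(P_s2||P_t2) + 1/2 KL(P_t2||P_s2).

    (The textbook Jensen-Shannon divergence mixes the two distributions; this
    loss symmetrizes KL directly, which already removes the asymmetry.)
    """
    if np.shape(p_s2) != np.shape(p_t2):
        raise ValueError("shape mismatch")
    return 0.5 * kl_divergence(p_s2, p_t2) + 0.5 * kl_divergence(p_t2, p_s2)


def _ce_from_logits(log_probs: Tensor, y: np.ndarray) -> Tensor:
    """Cross-entropy from log-softmax outputs; gradients stay alive even when
    the softmax saturates (the clipped-probability form would zero them)."""
    idx = (np.arange(len(y)), y.astype(int))
    return -(log_probs[idx]).mean()


def _sym_kl_from_logits(log_q: Tensor, p_data: np.ndarray) -> Tensor:
    """1/2 KL(Q||P) + 1/2 KL(P||Q) with Q = exp(log_q) on the tape."""
    pc = np.clip(p_data, EPS, 1.0)
    q = log_q.exp()
    kl_pq = Tensor(pc * np.log(pc)).sum(axis=-1).mean() - (
        (Tensor(pc) * log_q).sum(axis=-1).mean()
    )
    kl_qp = (q * (log_q - Tensor(np.log(pc)))).sum(axis=-1).mean()
    return 0.5 * kl_pq + 0.5 * kl_qp


def ema_update(
    state: TeacherStudentState,
    theta_s_new: list | None = None,
    alpha: float | None = None,
) -> TeacherStudentState:
    """theta_t' = alpha * theta_t + (1 - alpha) * theta_s', elementwise.

    ``alpha`` overrides ``state.ema_alpha`` for one update (the trainer uses
    this for the standard warm-up min(1 - 1/(step+1), alpha), under which the
    teacher begins as a plain running average of the student trajectory
    instead of clinging to its random initialization).  Batch-norm running
    statistics follow the same moving average so the teacher stays usable in
    inference mode.
    """
    a = state.ema_alpha if alpha is None else alpha
    src = theta_s_new if theta_s_new is not None else state.theta_s
    dst = state.teacher.parameters()
    if len(src) != len(dst):
        raise ValueError("parameter count mismatch")
    for t, s in zip(dst, src):
        s = np.asarray(s, dtype=float)
        if t.data.shape != s.shape:
            raise ValueError("parameter shape mismatch")
        t.data[...] = a * t.data + (1.0 - a) * s
    for tb, sb in zip(state.teacher.buffers(), state.student.buffers()):
        tb[...] = a * tb + (1.0 - a) * sb
    return state


# -- data plumbing -----------------------------------------------------------

def slices_to_array(samples, size: int = 32) -> np.ndarray:
    """Stack phantom slices into (N, 1, size, size), per-image standardized."""
    out = np.empty((len(samples), 1, size, size))
    for i, s in enumerate(samples):
        img = np.asarray(s.image, dtype=float) / 255.0
        H = img.shape[0]
        if H != size:
            img = ndimage.zoom(img, size / H, order=1)[:size, :size]
        img = (img - img.mean()) / (img.std() + 1e-8)
        out[i, 0] = img
    return out


def _random_flips(batch: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Label-preserving geometric augmentation (flips / 180-degree rotation)."""
    out = batch.copy()
    flips = rng.integers(0, 4, size=len(batch))
    for i, f in enumerate(flips):
        if f == 1:
            out[i] = out[i, :, :, ::-1]
        elif f == 2:
            out[i] = out[i, :, ::-1, :]
        elif f == 3:
            out[i] = out[i, :, ::-1, ::-1]
    return out


def _labels(samples) -> np.ndarray:
    return np.array([1 if s.usefulness_label == "US" else 0 for s in samples])


# -- training ----------------------------------------------------------------

def train_curation(
    labeled,
    unlabeled,
    config: ResNet7Config | None = None,
    epochs: int = 20,
    seed: int = 0,
    ema_alpha: float = 0.99,
    lr: float = 1e-3,
    batch_size: int = 32,
    augment_batches: bool = True,
) -> TeacherStudentState:
    """Train the student/teacher pair; deterministic for a fixed seed.

    ``labeled`` must be non-empty; an empty ``unlabeled`` set degrades
    gracefully to purely supervised training (l = l1).
    """
    if len(labeled) == 0:
        raise ValueError("at least one labeled sample is required")
    config = config or ResNet7Config()
    rng = np.random.default_rng(seed)
    student = ResNet7(config, seed=int(rng.integers(2**31)))
    teacher = ResNet7(config, seed=0)
    teacher.load_state_arrays([a.copy() for a in student.state_arrays()])
    state = TeacherStudentState(student=student, teacher=teacher, ema_alpha=ema_alpha)

    x1 = slices_to_array(labeled, config.input_size)
    y1 = _labels(labeled)
    x2 = (
        slices_to_array(unlabeled, config.input_size)
        if len(unlabeled)
        else np.empty((0, 1, config.input_size, config.input_size))
    )

    opt = nn.Adam(student.parameters(), lr=lr)
    losses = []
    n1, n2 = len(x1), len(x2)
    step = 0
    for _ in range(epochs):
        order1 = rng.permutation(n1)
        epoch_loss = 0.0
        n_batches = max(1, int(np.ceil(n1 / batch_size)))
        for b in range(n_batches):
            idx1 = order1[b * batch_size : (b + 1) * batch_size]
            if idx1.size == 0:
                continue
            xb = x1[idx1]
            if augment_batches:
                xb = _random_flips(xb, rng)
            student.set_training(True)
            ls1 = student.logits(Tensor(xb)).log_softmax(axis=1)
            l1 = _ce_from_logits(ls1, y1[idx1])
            if n2:
                idx2 = rng.choice(n2, size=min(batch_size, n2), replace=False)
                # student and teacher see independently augmented views of the
                # same unlabeled slices (label-preserving flips); identical
                # views degenerate into self-distillation
                xs2 = _random_flips(x2[idx2], rng) if augment_batches else x2[idx2]
                xt2 = _random_flips(x2[idx2], rng) if augment_batches else x2[idx2]
                ls2 = student.logits(Tensor(xs2)).log_softmax(axis=1)
                # consistency targets use batch statistics: early in training
                # the teacher's averaged parameters and stale running stats do
                # not form a working network in inference mode, and its
                # confidently wrong targets derail the student
                teacher.set_training(True)
                saved = [b.copy() for b in teacher.buffers()]
                p_t2 = teacher(Tensor(xt2)).data
                for buf, old in zip(teacher.buffers(), saved):
                    buf[...] = old
                loss = l1 + _sym_kl_from_logits(ls2, p_t2)
            else:
                loss = l1
            opt.zero_grad()
            loss.backward()
            opt.step()
            ema_update(state, alpha=min(1.0 - 1.0 / (step + 1), ema_alpha))
            step += 1
            epoch_loss += loss.item()
        losses.append(epoch_loss / n_batches)
    state.trained = True
    state.history["loss"] = losses
    return state


def split_slices(state: TeacherStudentState, samples, prob_threshold: float = 0.5) -> CurationResult:
    """Assign US/NS by teacher P(US) >= threshold; order US before NS."""
    if not state.trained:
        raise ValueError("curation state is untrained")
    x = slices_to_array(samples, state.teacher.config.input_size)
    state.teacher.set_training(False)
    chunks = [
        state.teacher(Tensor(x[i : i + 32])).data[:, 1] for i in range(0, len(x), 32)
    ]
    p_us = np.concatenate(chunks)
    is_us = p_us >= prob_threshold
    assignment = ["US" if u else "NS" for u in is_us]
    order = np.concatenate([np.flatnonzero(is_us), np.flatnonzero(~is_us)])
    return CurationResult(
        assignment=assignment,
        p_us=p_us,
        order=order,
        us_fraction=float(is_us.mean()),
        ns_fraction=float(1.0 - is_us.mean()),
    )
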