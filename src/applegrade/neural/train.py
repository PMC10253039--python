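"""Composite detection loss and a short sanity-training loop.

The loss is the standard YOLO recipe: binary cross-entropy on objectness over
every anchor cell, plus BCE on class scores and a squared-error box term at
the cells responsible for a ground-truth object.  Targets are assigned to the
grid cell containing the box centre, on the scale whose anchor best matches
the box, which is all a smoke-scale training run needs.
"""

from __future__ import annotations

import numpy as np

from .models import DetectionModel
from .tensor import Tensor

__all__ = ["yolo_loss", "smoke_train", "SGD"]

# stock YOLOv5 anchor sizes (pixels) per stride-8/16/32 scale
ANCHORS = (
    ((10, 13), (16, 30), (33, 23)),
    ((30, 61), (62, 45), (59, 119)),
    ((116, 90), (156, 198), (373, 326)),
)


def _bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Numerically stable mean BCE: softplus(x) - x*z elementwise."""
    t = Tensor(targets.astype(np.float32))
    abs_x = logits.relu() + (-logits).relu()
    softplus = logits.relu() + (1.0 + (-abs_x).exp()).log()
    return (softplus - logits * t).mean()


def assign_targets(
    boxes: list[np.ndarray],
    num_classes: int,
    grids: list[tuple[int, int]],
    img_size: int,
) -> list[dict]:
    """Build per-scale target maps from normalized (cls, cx, cy, w, h) boxes.

    Each ground-truth box is assigned to the scale whose best anchor has the
    smallest aspect mismatch, at the cell containing the box centre.
    """
    per_scale = [
        {
            "obj": np.zeros((len(boxes), 3, gh, gw), dtype=np.float32),
            "pos": [],  # (img, anchor, gy, gx, cls, tx, ty, tw, th)
        }
        for gh, gw in grids
    ]
    for img_idx, img_boxes in enumerate(boxes):
        for cls, cx, cy, w, h in img_boxes:
            wh = np.array([w, h]) * img_size
            best = (np.inf, 0, 0)
            for s, anchors in enumerate(ANCHORS):
                for a, (aw, ah) in enumerate(anchors):
                    ratio = max(wh[0] / aw, aw / max(wh[0], 1e-6), wh[1] / ah, ah / max(wh[1], 1e-6))
                    if ratio < best[0]:
                        best = (ratio, s, a)
            _, s, a = best
            gh, gw = grids[s]
            gx = min(int(cx * gw), gw - 1)
            gy = min(int(cy * gh), gh - 1)
            per_scale[s]["obj"][img_idx, a, gy, gx] = 1.0
            per_scale[s]["pos"].append(
                (img_idx, a, gy, gx, int(cls), cx * gw - gx, cy * gh - gy, w, h)
            )
    return per_scale


def yolo_loss(
    predictions: list[Tensor],
    boxes: list[np.ndarray],
    num_classes: int,
    img_size: int,
) -> Tensor:
    """Objectness + class + box loss over the three prediction scales."""
    grids = [(p.shape[2], p.shape[3]) for p in predictions]
    targets = assign_targets(boxes, num_classes, grids, img_size)
    total = Tensor(0.0)
    for pred, tgt in zip(predictions, targets):
        n, _, gh, gw = pred.shape
        p = pred.reshape(n, 3, 5 + num_classes, gh, gw)
        obj_logits = p[:, :, 4]
        total = total + _bce_with_logits(obj_logits, tgt["obj"])
        if tgt["pos"]:
            idx = np.array([(i, a, gy, gx) for i, a, gy, gx, *_ in tgt["pos"]])
            ii, aa, yy, xx = idx[:, 0], idx[:, 1], idx[:, 2], idx[:, 3]
            box_t = np.array([[tx, ty, tw, th] for *_, tx, ty, tw, th in tgt["pos"]], dtype=np.float32)
            cls_t = np.zeros((len(tgt["pos"]), num_classes), dtype=np.float32)
            for row, (_, _, _, _, c, *_) in enumerate(tgt["pos"]):
                cls_t[row, c] = 1.0
            p_pos = p[ii, aa, :, yy, xx]  # (P, 5+nc)
            box_pred = p_pos[:, :4].sigmoid()
            total = total + ((box_pred - Tensor(box_t)) ** 2).mean()
            total = total + _bce_with_logits(p_pos[:, 5:], cls_t)
    return total


class SGD:
    """Plain stochastic gradient descent with momentum."""

    def __init__(self, params, lr: float = 0.01, momentum: float = 0.9):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self._velocity = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        for p, v in zip(self.params, self._velocity):
            if p.grad is None:
                continue
            v *= self.momentum
            v += p.grad
            p.data -= self.lr * v

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


def smoke_train(
    model: DetectionModel,
    steps: int = 20,
    batch_size: int = 2,
    img_size: int = 64,
    lr: float = 0.02,
    seed: int = 0,
) -> list[float]:
    """Fit one fixed synthetic batch for ``steps`` SGD steps.

    Returns the loss trace.  This is a functional sanity check — gradients
    reach every parameter and the objective decreases — not a training
    recipe.
    """
    rng = np.random.default_rng(seed)
    nc = model.config.num_classes
    x = Tensor(rng.normal(0.5, 0.2, size=(batch_size, 3, img_size, img_size)))
    boxes = []
    for _ in range(batch_size):
        n_obj = rng.integers(1, 3)
        img_boxes = []
        for _ in range(n_obj):
            w, h = rng.uniform(0.2, 0.5, size=2)
            cx = rng.uniform(w / 2, 1 - w / 2)
            cy = rng.uniform(h / 2, 1 - h / 2)
            img_boxes.append((rng.integers(0, nc), cx, cy, w, h))
        boxes.append(np.array(img_boxes, dtype=np.float32))

    model.train()
    opt = SGD(model.parameters(), lr=lr)
    trace = []
    for _ in range(steps):
        opt.zero_grad()
        preds = model(x)
        loss = yolo_loss(preds, boxes, nc, img_size)
        loss.backward()
        opt.step()
        trace.append(float(loss.data))
    return trace
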