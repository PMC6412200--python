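"""Train the 1-D convolutional layout on raw 9-channel windows.

Builds CNN1 (5x1 temporal kernels, the nine sensor channels in depth),
trains it for 20 epochs with SGD on 8 synthetic subjects and evaluates on
2 held-out subjects — no feature engineering, no orientation handling.
About a minute on one CPU core.
"""

import numpy as np

import wearact as wa
from wearact.cnn import DEFAULT_SPECS, CnnLayout, build_network, evaluate_cnn, train_cnn

cohort = wa.make_cohort(n_train=8, n_test=2, fraction_rotated=0.0,
                        fraction_wws=0.0, master_seed=7)


def windows_of(subjects):
    mats, labels = [], []
    for s in subjects:
        ws = wa.segment_windows(s.recording, wa.build_labels(s.track))
        keep = [i for i, l in enumerate(ws.labels) if l is not None]
        mats.append(ws.data[keep])
        labels += [ws.labels[i] for i in keep]
    return np.vstack(mats), labels


X, y = windows_of(cohort.train)
Xt, yt = windows_of(cohort.test)

spec = DEFAULT_SPECS[CnnLayout.CNN1]
model = build_network(spec, seed=0)
for info in model.info:
    print(f"  {info.name:<8} out {str(info.output_shape):<14} {info.n_params:>9,} params")
print(f"total {model.n_params:,} parameters")

history = train_cnn(model, X, y, epochs=20, seed=0)
print(f"epoch 1  loss {history[0]['loss']:.3f} acc {history[0]['accuracy']:.3f}")
print(f"epoch 20 loss {history[-1]['loss']:.3f} acc {history[-1]['accuracy']:.3f}")

acc, confusion = evaluate_cnn(model, Xt, yt)
print(f"held-out accuracy {100 * acc:.1f}% on {len(yt)} windows")
print("row-normalized confusion (%):")
print(np.round(confusion, 1))

# The temporal widths shrink 68 -> 64 -> 60 -> 56 through the three valid
# 5-wide convolutions; the confusion matrix rows are percentages per true
# class (sit/stand, laying, walking, stairs, transition).
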