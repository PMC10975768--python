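"""Generate a synthetic sun-dried-kelp scene, augment it, and write labels.

Prints what the generator produced: how many strips were rendered, which
overlapping strips were merged into one collective label (as a human
annotator would when strips are indistinguishable), and how augmentation
affected the labels.
"""

import tempfile
from pathlib import Path

from kyolo import SceneSpec, augment, generate_scene
from kyolo.synthetic import write_labels, read_labels_yolo

spec = SceneSpec(size=320, altitude="mixed", overlap_prob=0.7,
                 merge_iou=0.4, seed=13)
scene = generate_scene(spec)
print(f"rendered strips : {sum(len(g) for g in scene.merged_groups)}")
print(f"labels          : {len(scene.boxes)} "
      f"({sum(1 for g in scene.merged_groups if len(g) > 1)} collective)")
print(f"merged groups   : {scene.merged_groups}")
# a collective label is one enclosing box covering several overlapping strips

aug = augment(scene, ["additive_noise", "random_rotation", "random_masking"],
              seed=3)
print(f"after augmentation: {len(aug.boxes)} labels "
      f"(masking drops labels with < 25% visible area)")

with tempfile.TemporaryDirectory() as d:
    txt = Path(d) / "scene.txt"
    write_labels(scene, txt, "yolo_txt")
    write_labels(scene, Path(d) / "scene.xml", "voc_xml")
    print("\nfirst YOLO label lines:")
    for line in txt.read_text().splitlines()[:3]:
        print(f"  {line}")
    assert len(read_labels_yolo(txt)) == len(scene.boxes)
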