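"""Build the stimulus set: Gaussian noise, targets, composites, framing.

Generates one noise canvas, a bank of schematic face targets, and the easy
(opacity 0.50) and difficult (opacity 0.20) composites, then draws the
elliptical frame and fixation cross and writes everything as PNGs.
"""

from pathlib import Path

import pareidoscope as ps

out = Path("example_output/stimuli")
out.mkdir(parents=True, exist_ok=True)

noise = ps.generate_noise(300, 350, mean=128, sd=30, seed=1)
print(f"noise canvas: {noise.pixels.shape[1]}x{noise.pixels.shape[0]} px, "
      f"mean {noise.pixels.mean():.1f}, sd {noise.pixels.std():.1f}")

bank = ps.make_target_bank("chimpanzee_face", n=20, seed=0)
print(f"target bank: {len(bank)} distinct {bank[0].pixels.shape[1]}x"
      f"{bank[0].pixels.shape[0]} px faces")

for label, opacity in [("easy", 0.50), ("difficult", 0.20), ("absent", 0.0)]:
    comp = ps.composite_target(noise, bank[0] if opacity else None, opacity)
    framed = ps.apply_frame_and_cross(comp)
    ps.save_png(framed.pixels, out / f"stimulus_{label}.png")
    print(f"  {label:9s} (opacity {opacity:.2f}) -> stimulus_{label}.png")

print(f"\nPNGs in {out}/ — 'absent' is what a test-trial stimulus looks like:")
print("pure noise inside the frame, nothing to find.")
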