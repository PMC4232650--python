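"""Count microaneurysms on a synthetic fundus image by both protocols.

Run:  python examples/count_microaneurysms.py
"""

from retinoquant import PhantomSpec, PixelCalibration, count_mas, extract_green, make_phantom

image, truth = make_phantom(PhantomSpec(seed=3, n_mas=15))
green = extract_green(image)
cal = PixelCalibration(microns_per_pixel=25.0)

morph = count_mas(green, cal, method="morphology")
hough = count_mas(green, cal, method="hough")

print(f"planted microaneurysms:       {truth.ma_count}")
print(f"morphology protocol count:    {morph.count}")
print(f"hough protocol count:         {hough.count}")
print()
print("first three hough detections (row, col, radius px, edge support):")
for c in hough.candidates[:3]:
    print(f"  ({c.center[0]:3d}, {c.center[1]:3d})  r={c.radius}  support={c.support:.2f}")
print()
print("Both protocols share one candidate mask (CLAHE -> top/bottom-hat ->")
print("Otsu -> inverted binarization -> vessel subtraction).  The morphology")
print("protocol keeps dots of 30-100 um equivalent diameter; the Hough")
print("protocol validates each dot's boundary as a circle whose accumulator")
print("peak approaches the expected perimeter pixel count.")
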