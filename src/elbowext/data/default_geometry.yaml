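# Default elbow-extensor path geometry ("default elbow geometry").
#
# Frame: humerus-fixed, right-handed, cm. Origin at the elbow joint center,
# hinge axis = +z, humerus along +y; the forearm lies along -y at full
# extension and flexion rotates ulna-fixed points counterclockwise about +z.
#
# Posterior is the -x half-plane. Each head runs from a humerus-fixed
# effective origin down the posterior
# arm, wraps a hinge-coaxial cylinder standing in for the trochlea/olecranon
# surface, and inserts on the olecranon of the ulna. The wrap radii and
# origin heights were calibrated (scripts/calibrate_geometry.py) so that the
# 0-130 degree mean tendon-excursion moment arms are 1.70 / 1.71 / 1.81 cm
# for MHT / LatHT / LngHT and the long head's musculotendon excursion over
# the full range is 21%.
name: default-elbow-extensors
reference:
  upper_arm_length: 30.0   # cm, acromion to lateral epicondyle
  forearm_length: 25.0     # cm, lateral epicondyle to ulnar styloid
muscles:
  MHT:
    origin: {xyz: [-1.70, 9.265356, 0.0], segment: humerus}
    via_points: []
    insertion: {xyz: [-1.70, -2.5, 0.0], segment: ulna}
    wraps:
      - kind: cylinder
        center: [0.0, 0.0, 0.0]
        axis: [0.0, 0.0, 1.0]
        radius: 1.70
        active_range: [0.0, 130.0]
        side: ccw
  LatHT:
    origin: {xyz: [-1.71, 17.051787, 0.0], segment: humerus}
    via_points: []
    insertion: {xyz: [-1.71, -2.5, 0.0], segment: ulna}
    wraps:
      - kind: cylinder
        center: [0.0, 0.0, 0.0]
        axis: [0.0, 0.0, 1.0]
        radius: 1.71
        active_range: [0.0, 130.0]
        side: ccw
  LngHT:
    origin: {xyz: [-1.81, 17.055999, 0.0], segment: humerus}
    via_points: []
    insertion: {xyz: [-1.81, -2.5, 0.0], segment: ulna}
    wraps:
      - kind: cylinder
        center: [0.0, 0.0, 0.0]
        axis: [0.0, 0.0, 1.0]
        radius: 1.81
        active_range: [0.0, 130.0]
        side: ccw
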