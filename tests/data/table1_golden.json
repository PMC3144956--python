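{
 "pol-mir-1": {
  "length": 61,
  "n_pairs": 23,
  "energy": -22.59,
  "dot_bracket": "((((((((((((((((..(((((((........))..))))).)))))))))))))))).."
 },
 "pol-let-7b": {
  "length": 76,
  "n_pairs": 29,
  "energy": -35.08,
  "dot_bracket": ".(((((((((((((((((((((....((((.((((........))))..))))))))))))))))))))))))).."
 },
 "pol-let-7c": {
  "length": 76,
  "n_pairs": 28,
  "energy": -36.91,
  "dot_bracket": ".(((((((((((((((((((((.(((((((.......))))))).........))))))))))))))))))))).."
 },
 "pol-let-7d": {
  "length": 70,
  "n_pairs": 21,
  "energy": -15.7,
  "dot_bracket": ".(((.(((..(((((((((((((((..............))))....)))))))))))..))).)))..."
 },
 "pol-mir-9": {
  "length": 57,
  "n_pairs": 20,
  "energy": -21.15,
  "dot_bracket": "..(((((((.(((((((.((((((.......)))))).))))))).)))))))...."
 },
 "pol-mir-10d": {
  "length": 63,
  "n_pairs": 19,
  "energy": -17.2,
  "dot_bracket": "..((((..((((.(((((...((((((.........)))))).))))).)))).))))....."
 },
 "pol-mir-21": {
  "length": 61,
  "n_pairs": 21,
  "energy": -21.7,
  "dot_bracket": "(((((..((((((((.(((((..(((.......)))...))))).)))))))).))))).."
 },
 "pol-mir-22a": {
  "length": 67,
  "n_pairs": 23,
  "energy": -25.69,
  "dot_bracket": "..(((((((((((((((((.((((((.................)))))))))))).)))))))))))"
 },
 "pol-mir-122": {
  "length": 63,
  "n_pairs": 23,
  "energy": -25.55,
  "dot_bracket": "(((((.(((((((.(((((((((((............))))))))))).))))))).)))))."
 },
 "pol-mir-124": {
  "length": 60,
  "n_pairs": 21,
  "energy": -17.09,
  "dot_bracket": ".((((((((.(((..(((((((....(((....))))))))))..))).))))))))..."
 },
 "pol-mir-133b": {
  "length": 60,
  "n_pairs": 21,
  "energy": -18.42,
  "dot_bracket": "((((((..((.((.(((((((((((....)))....)))))))).)).))..)))))).."
 },
 "pol-mir-140": {
  "length": 62,
  "n_pairs": 23,
  "energy": -32.48,
  "dot_bracket": "..(((((((((((((.(((((((..(((......)))))))))).)))))))))))))...."
 },
 "pol-mir-144": {
  "length": 68,
  "n_pairs": 25,
  "energy": -25.83,
  "dot_bracket": ".((((((((((((((..(((((((.((((.......))))..))))))).)))))))))....)))))"
 },
 "pol-mir-182": {
  "length": 65,
  "n_pairs": 19,
  "energy": -20.24,
  "dot_bracket": ".(((((((...(((((((...(((((..............))))))))))))...)))))))..."
 },
 "pol-mir-199-1": {
  "length": 61,
  "n_pairs": 22,
  "energy": -21.68,
  "dot_bracket": ".(((((((.((((((((.(((.((((........)))).))))))))))).)))))))..."
 },
 "pol-mir-199-2": {
  "length": 61,
  "n_pairs": 21,
  "energy": -20.43,
  "dot_bracket": ".(((((((.((((((((.((((((........)))....))))))))))).)))))))..."
 },
 "pol-mir-203": {
  "length": 60,
  "n_pairs": 24,
  "energy": -21.37,
  "dot_bracket": "(((((((((.((((.(((.((((((((...)))..)))))))).)))).))))))))).."
 },
 "pol-mir-206a": {
  "length": 60,
  "n_pairs": 21,
  "energy": -22.23,
  "dot_bracket": "((((((((((((((((..(((((.............))))).)))))))))))))))).."
 },
 "pol-mir-219": {
  "length": 64,
  "n_pairs": 23,
  "energy": -18.48,
  "dot_bracket": "(((.((((((..((((((((((((((.........))))..))))))))))..))))))))).."
 },
 "pol-mir-221": {
  "length": 65,
  "n_pairs": 24,
  "energy": -27.92,
  "dot_bracket": ".((((((((((.(((((((((....(((((........)))))))))))))).)))))))))).."
 }
}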