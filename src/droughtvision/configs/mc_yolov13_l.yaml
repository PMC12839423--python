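# MC-YOLOv13-L architecture table.
# Columns: id, from (source layer ids; -1 = previous), module (registry key),
# args (argument vector), params (reference per-layer trainable-parameter
# count; the column sums to 3477567). Plain Conv rows are reproduced exactly
# by the built network (conv-without-bias + batch norm); composite blocks are
# this package's own designs and carry the reference count for accounting.
nc: 4
input_side: 640
layers:
  - {id: 0,  from: -1,        params: 464,     module: Conv,            args: [3, 16, 3, 2]}
  - {id: 1,  from: -1,        params: 2368,    module: Conv,            args: [16, 32, 3, 2, 1, 2]}
  - {id: 2,  from: -1,        params: 6424,    module: C3k2_MSLA,       args: [32, 64, 1, false, 0.25]}
  - {id: 3,  from: -1,        params: 9344,    module: Conv,            args: [64, 64, 3, 2, 1, 4]}
  - {id: 4,  from: -1,        params: 23724,   module: C3k2_MSLA,       args: [64, 128, 1, false, 0.25]}
  - {id: 5,  from: -1,        params: 17792,   module: DSConv,          args: [128, 128, 3, 2]}
  - {id: 6,  from: -1,        params: 174720,  module: A2C2f,           args: [128, 128, 2, true, 4]}
  - {id: 7,  from: -1,        params: 34432,   module: DSConv,          args: [128, 256, 3, 2]}
  - {id: 8,  from: -1,        params: 677120,  module: A2C2f,           args: [256, 256, 2, true, 1]}
  - {id: 9,  from: -1,        params: 1121792, module: CMUNeXt,         args: [256, 256, 1]}
  - {id: 10, from: [4, 6, 8], params: 273536,  module: HyperACE,        args: [128, 128, 1, 4, true, true, 0.5, 1, both]}
  - {id: 11, from: -1,        params: 0,       module: Upsample,        args: [null, 2, nearest]}
  - {id: 12, from: 10,        params: 33280,   module: DownsampleConv,  args: [128]}
  - {id: 13, from: [6, 10],   params: 1,       module: FullPAD_Tunnel,  args: []}
  - {id: 14, from: [4, 11],   params: 1,       module: FullPAD_Tunnel,  args: []}
  - {id: 15, from: [9, 12],   params: 1,       module: FullPAD_Tunnel,  args: []}
  - {id: 16, from: -1,        params: 0,       module: Upsample,        args: [null, 2, nearest]}
  - {id: 17, from: [-1, 13],  params: 0,       module: Concat,          args: [1]}
  - {id: 18, from: -1,        params: 96600,   module: C3k2_MSLA,       args: [384, 128, 1, true]}
  - {id: 19, from: [-1, 10],  params: 1,       module: FullPAD_Tunnel,  args: []}
  - {id: 20, from: 18,        params: 0,       module: Upsample,        args: [null, 2, nearest]}
  - {id: 21, from: [-1, 14],  params: 0,       module: Concat,          args: [1]}
  - {id: 22, from: -1,        params: 29232,   module: C3k2_MSLA,       args: [256, 64, 1, true]}
  - {id: 23, from: 11,        params: 8320,    module: Conv,            args: [128, 64, 1, 1]}
  - {id: 24, from: [22, 23],  params: 1,       module: FullPAD_Tunnel,  args: []}
  - {id: 25, from: -1,        params: 36992,   module: Conv,            args: [64, 64, 3, 2]}
  - {id: 26, from: [-1, 19],  params: 0,       module: Concat,          args: [1]}
  - {id: 27, from: -1,        params: 72024,   module: C3k2_MSLA,       args: [192, 128, 1, true]}
  - {id: 28, from: [-1, 10],  params: 1,       module: FullPAD_Tunnel,  args: []}
  - {id: 29, from: 27,        params: 147712,  module: Conv,            args: [128, 128, 3, 2]}
  - {id: 30, from: [-1, 15],  params: 0,       module: Concat,          args: [1]}
  - {id: 31, from: -1,        params: 280232,  module: C3k2_MSLA,       args: [384, 256, 1, true]}
  - {id: 32, from: [-1, 12],  params: 1,       module: FullPAD_Tunnel,  args: []}
  - {id: 33, from: [24, 28, 32], params: 431452, module: Detect,        args: [4, [64, 128, 256]]}
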