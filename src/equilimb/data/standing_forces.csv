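name,kind,force_N,attaches_femur,muscle_group
m. tensor fasciae latae,muscle,2158,1,
m. gastrocnemius,muscle,1550,1,
m. pectineus,muscle,1010,1,
m. superficial digital flexor,muscle,905,1,
m. vastus medialis,muscle,840,1,quadriceps
m. biceps femoris,muscle,834,0,
m. gluteus superficialis,muscle,445,1,
m. peroneus tertius,muscle,285,1,
m. gluteus medius,muscle,119,1,
m. vastus lateralis,muscle,66,1,quadriceps
m. adductor,muscle,63,1,
m. gracilis,muscle,40,0,
m. gluteus profundus,muscle,32,1,
m. semimembranosus,muscle,32,1,
m. rectus femoris,muscle,32,0,quadriceps
m. semitendinosus,muscle,28,0,
m. sartorius,muscle,24,0,
m. extensor digitalis,muscle,16,1,
m. vastus intermedius,muscle,13,1,quadriceps
lig. patellae intermediale,ligament,2092,0,
lig. patellae medialis,ligament,170,0,
lig. patellae laterale,ligament,0,0,
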