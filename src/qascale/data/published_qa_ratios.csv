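concept,qwen_positive,qwen_negative,qwen_null,baichuan_positive,baichuan_negative,baichuan_null
Menstrual color,,,0.00,,,0.67
Menstrual flow,,,0.00,,,0.80
Pregnancy weight gain,,,1.60,,,2.53
Abdominal bloating,26.27,73.73,0.00,38.40,61.60,0.00
Abdominal pain,49.00,51.00,0.00,43.13,52.00,4.87
Amniocentesis,1.00,99.00,0.00,0.73,98.87,0.40
Aspirin use,1.40,98.60,0.00,1.40,98.60,0.00
Bilateral adnexal masses,4.87,95.13,0.00,0.73,99.20,0.07
Bilateral lower limb edema,51.53,48.47,0.00,4.87,95.13,0.00
Blood glucose screening,17.87,82.13,0.00,28.13,71.40,0.47
Cervical secretions,3.53,96.47,0.00,3.67,96.33,0.00
Chest tightness,2.87,97.13,0.00,4.40,95.53,0.07
Cold or flu,1.87,98.13,0.00,3.07,96.93,0.00
Convulsions,2.27,97.73,0.00,0.33,99.67,0.00
Dizziness,7.13,92.87,0.00,1.87,98.13,0.00
Drinking,0.00,100.00,0.00,0.00,100.00,0.00
Early pregnancy reaction or symptoms,85.93,14.07,0.00,47.53,52.13,0.33
Family history (asthma),0.07,99.93,0.00,1.93,98.07,0.00
Family history (autoimmune disease),0.20,99.80,0.00,3.07,96.93,0.00
Family history (diabetes mellitus),1.67,98.33,0.00,2.33,97.67,0.00
Family history (drug allergy),0.01,99.99,0.00,5.67,94.33,0.00
Family history (heart disease),1.60,98.40,0.00,2.27,97.73,0.00
Family history (hematologic disease),0.13,99.87,0.00,0.73,98.87,0.40
Family history (hypertension),3.87,96.13,0.00,3.93,96.07,0.00
Family history (kidney disease),0.07,99.93,0.00,1.40,98.53,0.07
Family history (mental illness),0.07,99.93,0.00,0.47,99.47,0.07
Family history (neurological disease),0.47,99.53,0.00,0.73,98.80,0.47
Family history (preeclampsia),0.12,99.88,0.00,2.60,97.40,0.00
Family history (rheumatic disease),0.07,99.93,0.00,1.47,98.53,0.00
Fetal paternal drinking history,0.00,100.00,0.00,0.07,99.93,0.00
Fetal paternal history of genetic diseases,1.00,99.00,0.00,0.87,99.07,0.07
Fetal paternal smoking history,0.00,100.00,0.00,0.07,99.93,0.00
Fever,9.67,90.33,0.00,1.93,98.07,0.00
G6PD,3.33,96.67,0.00,2.53,97.47,0.00
Headache,2.80,97.20,0.00,0.80,99.13,0.07
Insomnia,0.60,99.40,0.00,1.20,98.47,0.33
Mediterranean anemia screening,8.27,91.73,0.00,17.60,82.27,0.13
Palpitations,1.53,98.47,0.00,3.07,96.93,0.00
Personal history (antiphospholipid syndrome),0.07,99.93,0.00,0.07,99.93,0.00
Personal history (chronic kidney disease),0.80,99.20,0.00,1.07,98.93,0.00
Personal history (diabetes mellitus),0.60,99.40,0.00,0.13,99.87,0.00
Personal history (drug allergy),10.53,89.47,0.00,39.80,60.20,0.00
Personal history (dysmenorrhea),24.40,75.60,0.00,21.20,78.80,0.00
Personal history (food allergy),5.13,94.87,0.00,8.07,91.93,0.00
Personal history (heart disease),1.67,98.33,0.00,0.47,99.53,0.00
Personal history (hematologic disease),0.00,100.00,0.00,0.07,99.93,0.00
Personal history (hypertension),7.40,92.60,0.00,0.93,99.07,0.00
Personal history (infectious disease),1.93,98.07,0.00,3.80,96.20,0.00
Personal history (preeclampsia),0.93,99.07,0.00,0.87,99.13,0.00
Personal history (surgery history),35.67,64.33,0.00,36.27,63.67,0.07
Personal history (systemic lupus erythematosus),0.20,99.80,0.00,0.20,99.80,0.00
Personal history (thalassemia),1.00,99.00,0.00,0.80,99.13,0.07
Personal history (trauma history),8.80,91.20,0.00,2.87,97.13,0.00
Personal history (viral hepatitis),6.07,93.93,0.00,6.20,93.80,0.00
Poor pregnancy history (induced abortion),0.07,99.93,0.00,0.13,99.87,0.00
Poor pregnancy history (miscarriage),0.47,99.53,0.00,0.47,99.53,0.00
Poor pregnancy history (premature birth),0.27,99.73,0.00,0.27,99.73,0.00
Prenatal screening,31.13,68.87,0.00,15.87,83.40,0.73
Regular prenatal check-ups,96.20,3.80,0.00,96.80,3.13,0.07
Smoking,0.07,99.93,0.00,0.07,99.93,0.00
Threatened abortion,6.20,93.80,0.00,5.80,94.00,0.20
Umbilical cord blood ratio,0.00,100.00,0.00,0.00,100.00,0.00
Use of antihypertensive drugs,1.73,98.27,0.00,2.13,97.87,0.00
Use of progestogen drugs,13.47,86.53,0.00,14.40,85.53,0.07
Vaginal bleeding,81.07,18.93,0.00,22.60,77.27,0.13
Vaginal discharge,33.00,67.00,0.00,48.47,51.53,0.00
Vaginal infection,25.27,74.73,0.00,16.20,82.73,1.07
Vaginal secretions,16.60,83.40,0.00,16.73,83.27,0.00
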