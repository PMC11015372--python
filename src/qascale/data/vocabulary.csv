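term,domain_tag
头痛,Clinical finding
headache,Clinical finding
头晕,Clinical finding
dizziness,Clinical finding
腹痛,Clinical finding
abdominal pain,Clinical finding
腹胀,Clinical finding
阴道流血,Clinical finding
阴道出血,Clinical finding
vaginal bleeding,Clinical finding
双下肢水肿,Clinical finding
水肿,Clinical finding
edema,Clinical finding
发热,Clinical finding
fever,Clinical finding
胸闷,Clinical finding
心悸,Clinical finding
失眠,Clinical finding
抽搐,Clinical finding
痛经,Clinical finding
dysmenorrhea,Clinical finding
药物过敏,Clinical finding
drug allergy,Clinical finding
食物过敏,Clinical finding
手术史,Clinical finding
外伤史,Clinical finding
高血压,Clinical finding
家族高血压,Clinical finding
hypertension,Clinical finding
糖尿病,Clinical finding
diabetes mellitus,Clinical finding
先兆流产,Clinical finding
早孕反应,Clinical finding
吸烟,Clinical finding
smoking,Clinical finding
饮酒,Clinical finding
孕期增重,Observable entity
pregnancy weight gain,Observable entity
月经颜色,Observable entity
月经量,Observable entity
体温,Observable entity
血压,Observable entity
G6PD,Observable entity
地中海贫血筛查,Procedure
羊膜腔穿刺,Procedure
剖宫产术,Procedure
amniocentesis,Procedure
产前检查,Procedure
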